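"""Read/write annotated transcripts and metric outputs as stable text.

The canonical transcript format is UTF-8 tab-separated text, one speech act
per row, with the fixed header::

    dialogue_id  speaker  epsilon  content  act_type  x  y  delta_task
    delta_interlocutor  decisive

Additional objects of analysis travel in optional trailing columns named
``delta_<object>``.  TSV (not CSV) because utterance text routinely
contains commas; tabs, newlines and backslashes inside content are escaped
(``\\t``, ``\\n``, ``\\\\``) so a plain split round-trips verbatim.
Line endings are normalized to ``\\n``.

Metric series and matrices serialize to JSON or TSV.  The JSON schema for
a metric series is::

    {"granularity": str, "object_id": str,
     "points": [{"index": int, "vergence": float,
                 "celerity": float, "n_acts": int}, ...]}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Union

from .core import ActType, Address, Dialogue, SpeechAct, build_dialogue, validate_dialogue
from .metrics import MetricPoint, MetricSeries

__all__ = [
    "TranscriptError",
    "read_transcript",
    "write_transcript",
    "write_metrics",
    "read_metrics",
    "BASE_COLUMNS",
]

BASE_COLUMNS = [
    "dialogue_id",
    "speaker",
    "epsilon",
    "content",
    "act_type",
    "x",
    "y",
    "delta_task",
    "delta_interlocutor",
    "decisive",
]


class TranscriptError(ValueError):
    """Malformed transcript file; the message names the offending row."""


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(text: str) -> str:
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            if nxt == "t":
                out.append("\t")
                i += 2
                continue
            if nxt == "n":
                out.append("\n")
                i += 2
                continue
            if nxt == "\\":
                out.append("\\")
                i += 2
                continue
        out.append(ch)
        i += 1
    return "".join(out)


def _parse_int(value: str, column: str, row: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise TranscriptError(f"row {row}: column {column!r} must be an integer, got {value!r}") from None


def _parse_flag(value: str, column: str, row: int) -> int:
    v = _parse_int(value, column, row)
    if v not in (0, 1):
        raise TranscriptError(f"row {row}: column {column!r} must be 0 or 1, got {v}")
    return v


def read_transcript(path: Union[str, Path]) -> Dialogue:
    """Parse a transcript TSV into a validated Dialogue.

    Raises
    ------
    TranscriptError
        On a missing/misordered header, non-integer numeric fields, unknown
        act types, an empty body, or any validation error (all reported
        with 1-based row numbers).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8").replace("\r\n", "\n").replace("\r", "\n")
    lines = [ln for ln in text.split("\n") if ln != ""]
    if not lines:
        raise TranscriptError("empty file: transcript needs a header row")
    header = lines[0].split("\t")
    if header[: len(BASE_COLUMNS)] != BASE_COLUMNS:
        raise TranscriptError(
            f"row 1: header must start with {BASE_COLUMNS}, got {header[:len(BASE_COLUMNS)]}"
        )
    extra = header[len(BASE_COLUMNS) :]
    for col in extra:
        if not col.startswith("delta_"):
            raise TranscriptError(f"row 1: unexpected extra column {col!r} (expected delta_<object>)")
    if len(lines) == 1:
        raise TranscriptError("transcript has a header but no speech acts")

    acts = []
    dialogue_id = None
    for row_no, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise TranscriptError(
                f"row {row_no}: expected {len(header)} columns, got {len(fields)}"
            )
        rec = dict(zip(header, fields))
        if dialogue_id is None:
            dialogue_id = rec["dialogue_id"]
        try:
            act_type = ActType.parse(rec["act_type"])
        except ValueError as exc:
            raise TranscriptError(f"row {row_no}: {exc}") from None
        polarity = {
            "task": _parse_flag(rec["delta_task"], "delta_task", row_no),
            "interlocutor": _parse_flag(rec["delta_interlocutor"], "delta_interlocutor", row_no),
        }
        for col in extra:
            polarity[col[len("delta_") :]] = _parse_flag(rec[col], col, row_no)
        x = _parse_int(rec["x"], "x", row_no)
        y = _parse_int(rec["y"], "y", row_no)
        try:
            address = Address(x, y)
        except ValueError as exc:
            raise TranscriptError(f"row {row_no}: {exc}") from None
        acts.append(
            SpeechAct(
                speaker=rec["speaker"],
                epsilon=_parse_int(rec["epsilon"], "epsilon", row_no),
                content=_unescape(rec["content"]),
                act_type=act_type,
                address=address,
                polarity=polarity,
                decisivity=_parse_flag(rec["decisive"], "decisive", row_no),
            )
        )

    acts.sort(key=lambda a: a.epsilon)
    try:
        dialogue = build_dialogue(acts, identifier=dialogue_id or path.stem)
    except ValueError as exc:
        raise TranscriptError(str(exc)) from None
    violations = [v for v in validate_dialogue(dialogue) if v.severity == "error"]
    if violations:
        msgs = "; ".join(f"epsilon={v.epsilon}: {v.message}" for v in violations[:5])
        raise TranscriptError(f"transcript fails validation: {msgs}")
    return dialogue


def write_transcript(dialogue: Dialogue, path: Union[str, Path]) -> None:
    """Serialize a Dialogue to transcript TSV (read_transcript inverse)."""
    extra_objects = [o for o in dialogue.objects() if o not in ("task", "interlocutor")]
    header = BASE_COLUMNS + [f"delta_{o}" for o in extra_objects]
    rows = ["\t".join(header)]
    for a in dialogue.acts():
        fields = [
            dialogue.identifier,
            a.speaker,
            str(a.epsilon),
            _escape(a.content),
            a.act_type.value,
            str(a.address.x),
            str(a.address.y),
            str(a.delta("task")),
            str(a.delta("interlocutor")),
            str(a.decisivity),
        ] + [str(a.delta(o)) for o in extra_objects]
        rows.append("\t".join(fields))
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8", newline="\n")


def _round6(x: float) -> float:
    return float(f"{float(x):.6g}")


def _series_to_obj(series: MetricSeries) -> dict:
    return {
        "granularity": series.granularity,
        "object_id": series.object_id,
        "points": [
            {
                "index": int(p.index),
                "vergence": _round6(p.vergence),
                "celerity": _round6(p.celerity),
                "n_acts": int(p.n_acts),
            }
            for p in series
        ],
    }


def _jsonify(obj):
    if isinstance(obj, MetricSeries):
        return _series_to_obj(obj)
    if isinstance(obj, Mapping):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, float):
        return _round6(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_metrics(obj, path: Union[str, Path], format: str = "json") -> None:
    """Write a MetricSeries (or a mapping of named results) to JSON or TSV.

    Floats are formatted at 6 significant digits so identical inputs give
    byte-identical files.
    """
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return
    if format == "tsv":
        if isinstance(obj, MetricSeries):
            rows = ["index\tvergence\tcelerity\tn_acts"]
            for p in obj:
                rows.append(f"{p.index}\t{_round6(p.vergence):.6g}\t{_round6(p.celerity):.6g}\t{p.n_acts}")
        elif isinstance(obj, Mapping):
            rows = ["key\tvalue"]
            for k, v in obj.items():
                v = _round6(v) if isinstance(v, float) else v
                rows.append(f"{k}\t{v}")
        else:
            raise TypeError(f"cannot write {type(obj).__name__} as TSV")
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
        return
    raise ValueError(f"unknown format {format!r}; use 'json' or 'tsv'")


def read_metrics(path: Union[str, Path]):
    """Read back a JSON metrics file; metric-series objects are revived."""
    obj = json.loads(Path(path).read_text(encoding="utf-8"))

    def revive(o):
        if isinstance(o, dict) and set(o) == {"granularity", "object_id", "points"}:
            return MetricSeries(
                o["granularity"],
                o["object_id"],
                [
                    MetricPoint(p["index"], p["vergence"], p["celerity"], p["n_acts"])
                    for p in o["points"]
                ],
            )
        if isinstance(o, dict):
            return {k: revive(v) for k, v in o.items()}
        return o

    return revive(obj)
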