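# Methods

## Data model and assumptions

A dialogue is a roster of ≥ 2 participants plus a hierarchy of planes →
concatenations → speech acts. Dialogical time ε is a 1-based global index;
transcripts that index pre-task talk with zero or negative ε are accepted
and shifted to a 1-based index, order preserved. Concatenation membership
is by the x coordinate of the address, not by contiguity: a theme may be
returned to later in the exchange (in the packaged fixture the marriage
theme holds ε = 3 and ε = 8). A theme opened in reaction to a deep act of
another theme may start at y > 1; the cells above it stay empty.

Polarity is stored per object of analysis as a mapping (`task`,
`interlocutor`, and any further `delta_<object>` columns of the transcript
format), because the same act can prove orientation toward one object and
not another. The binary coding δ ∈ {0, 1} is used throughout; no
intermediate level exists. Nonverbal actions (laughter, gestures, singing)
are ordinary speech acts, conventionally DO or MK with bracketed content.

The structural rule **d = 1 ⇒ δ_task = 1** (a decisive act is necessarily
task-polarized) is what makes the primacy inequality C ≤ V a theorem
rather than an empirical tendency. Validation treats a violation of the
rule as a data error to be reported, never silently corrected; the
literature names the inequality inconsistently (primacy of celerity
vs. primacy of vergence), but the content is the single inequality C ≤ V
and that is what `primacy_check` verifies. Validation never raises — it
returns a list of violation records (errors, plus warnings for polarity
entries that default to 0) so that annotation problems surface with the
offending ε.

The interaction-state description Ψ(ξ, ε, σ_n) has no closed form; the
package houses its arguments (address, time, act type and optional
per-act state annotations) without evaluating it.

## Kinetic metrics

Vergence and celerity are plain proportions over a segment (whole
dialogue, concatenation, or trailing window); both are undefined on an
empty act set and raise rather than return NaN. The divergence threshold
0.5 is reported alongside results but never branched on.

Running vergence supports a trailing window (default **20 acts**) and a
cumulative mode. The default window is sized so that regime changes stay
visible at typical task-dialogue lengths of a few hundred acts: shorter
windows are noisy at the per-act Bernoulli variance, much longer ones
smear a mid-dialogue regime change over most of the series.
"Vergence toward the interlocutor" for one speaker is running/whole
vergence restricted to that speaker's acts with object `interlocutor`.

The V–C coupling is the Pearson correlation over paired per-segment
values, with a two-tailed p from the exact t transform at df = n − 2.
Fewer than 3 points, or a constant V or C series, is a degenerate input
and raises (not NaN): a correlation on a constant margin is meaningless,
and silently returning a number invites misreading.

## Topological encodings

`encode_matrix` places each act's content at its (x, y) address (duplicate
addresses are an error). Matrices serialize as TSV with x as columns and
y as rows, mirroring the tabular layout of worked examples in the field.

The occupancy matrix of a subject group records, per cell, the fraction of
subjects whose trajectory visits it at least once; repeat visits count
once, so values are exactly 1 for universal cells and exactly 0 for
unvisited ones, invariant to trajectory order.

## Graded-prompting cooperation scoring

The three subtasks (basket / door / syllogism) each escalate through
exactly three prompt levels; a response is the level at which the subject
complied (0–2) or 3 for never. The canonical grid walks

- level 0: (1,1) → (1,2)
- level 1: (1,1) → (2,2) → (2,3) → (1,2)
- level 2: (1,1) → (2,2) → (2,3) → (3,4) → (3,5) → (1,2)
- level 3: (1,1) → (2,2) → (2,3) → (3,4) → (3,5) → (4,6)

are a convention of this package, chosen so that every position the
protocol distinguishes is reachable, intermediate stages are always
visited in order, and the five-subject group fractions (0.2 … 1.0) are
expressible. Whether a subject who "jumps" a level visibly passes the
intermediate stage is unobservable from level-coded data; the automaton
visits all intermediate positions. A clarification request at level ≥ 1
inserts the (3,4)/(3,5) question–answer exchange when the path does not
already pass through it. The grid is fixed at 4 × 6, the smallest grid
containing all named positions; extents beyond that are not meaningful.
The packaged group-response table encodes the published *descriptions* of
the two five-subject cohorts as level records; it is an encoding
convention, not raw data, and one cohort/subtask cell (control–syllogism)
cannot satisfy every printed percentage simultaneously under any level
assignment — the packaged encoding matches the per-stage fractions (0.8
indirect, 0.6 direct, one failure) and is documented as such.

## The recurrent vergence forecaster

A single-layer Elman network:

    h_ε = tanh(W_xh x_ε + W_hh h_{ε−1} + b_h)
    V̂_ε = σ(W_hy h_ε + b_y)

The logistic output guarantees V̂ ∈ [0, 1] by construction. The per-step
input x_ε is **(ε / ε_max, V_{ε−1})**: normalized dialogical time plus the
previous vergence value — observed while conditioning (teacher forcing),
the model's own prediction while free-running. Feeding the previous value
back in is a deliberate design choice: a time-only input would make the
hidden state a deterministic function of ε, so re-conditioning on observed
values and counterfactual interventions could not influence the forecast
at all. The first step bootstraps on its own value.

Training: MSE loss, full-sequence backpropagation through time, full-batch
gradient descent with a global gradient-norm clip (default 5.0) guarding
long sequences. Defaults: H = 8 hidden units, learning rate 0.01, 2000
epochs, weights initialized uniformly in [−0.5, 0.5] scaled by 1/√H from
a seeded generator (default seed 1459549), zero biases and zero initial
hidden state. The same seed yields bit-identical parameters. A non-finite
loss raises a divergence error naming the epoch and learning rate. No
claim of weight identifiability is made — evaluation is behavioral
(attractor fitting, trend following, intervention ordering), not
parametric.

Rolling forecasts free-run `stride` steps (default 3, "adjusting every
three speech acts"), recording the predictions, then replay the observed
values of the block to re-condition the hidden state before the next
block; `stride = remaining length` degenerates to a pure free run and
`stride = 1` to one-step-ahead prediction.

A counterfactual "prompt" forecast inserts one positively polarized act
into the polarity stream at the intervention ε, recomputes the
trailing-window conditioning series, truncates it to the original length
(so both forecasts share a time axis), and re-runs the rolling protocol.
While the inserted act remains inside the trailing window the
counterfactual conditioning value dominates the factual one pointwise
(strictly wherever the displaced act had δ = 0); afterwards the series is
the factual one lagged by a single act. How a prompt act mechanistically
enters the model is underdetermined by the recurrence itself; routing it
through the conditioning series is an interpretation, flagged as such.

## Two-group comparisons from summaries

`summary_ttest` computes the independent two-sample t-test from (mean, SD,
n) per group, pooled-variance by default (df = n_a + n_b − 2) or Welch
with Satterthwaite df; with two groups the one-way ANOVA is the identical
test (F = t², same p), so one operation serves tables whose rows are
labelled either way and exposes both statistics. Pooled is the default
because it reproduces the recoverable entries of the packaged cohort
table (Age p ≈ 0.69, visuo-spatial index p ≈ 0.003). Several other
printed p-values of that table (VC, GAI, IQ, ToM) are *not* recoverable
from the printed summaries under any two-group test on means —
recomputation gives ≈ 0.02–0.04 where < 0.001–0.002 is printed — and are
therefore excluded from reproduction checks; they presumably derive from
raw data or a different procedure. Both SDs zero is a degenerate input
and raises.

## Synthetic dialogue generator

The generator emulates the statistical structure of two-party task
dialogues: per-speaker act-type distributions, Bernoulli task and
interlocutor polarity (per speaker and per phase), decisivity drawn only
for task-positive acts (so C ≤ V holds on everything generated), turn
persistence 0.3 (speakers hold the floor in short runs), and an optional
change point at which the task-polarity probability jumps — the
"prompt"-regime scenario. Defaults (p_task = 0.8, p_interlocutor = 0.7,
p(d=1|δ=1) = 0.6, 10 concatenations of 5–15 acts) describe an ordinarily
cooperative task dialogue of a few hundred acts; the divergence scenario
used in regime checks is p_task 0.9 → 0.2 at ε = 150 of 300 acts,
window 20. Content strings are placeholders; nothing downstream inspects
text. One seeded generator drives each call; the seed is recorded in the
dialogue's metadata.

What the generator does **not** emulate: real lexical content, rhetorical
relations, annotator disagreement, non-stationarity beyond a single step
change, or the correlation structure between act type and polarity that
real clinical dialogues exhibit. Passing tests therefore demonstrate the
correctness and calibration of the pipeline under known generating
conditions, not clinical validity on real transcripts.

## Problem sizes and numerical choices in the checks

The statistical test batteries use: 1000 random configurations for the
primacy sweep (1–4 concatenations of 1–6 acts each); 10 000 acts for
binomial recovery of the polarity rate (3-σ band); 100 random parameter
draws (H ≤ 5) for step-exact agreement of the recurrence with an
independent plain-loop evaluation at 1e−10; and 20 replicates of the
divergence scenario for the intervention-ordering check, each training
for 800 epochs — the ordering is a paired comparison under identical
weights and hidden state, so it is insensitive to the exact epoch count
once the input–output map is learned. Serialized metric values are
written at 6 significant digits so identical runs give byte-identical
files.

## Interfaces

The forecaster follows the scikit-learn estimator idiom
(`get_params`/`set_params`, fitted attributes with a trailing underscore,
`fit`/`predict`), composing with sklearn tooling; the remaining operations
are plain functions over the domain types, which matches their
non-fit/predict shape. The CLI (`twotk analyze / topology / forecast /
testasap / simulate / groupstats`) is a thin layer over the library; a
YAML config file can supply defaults, explicit flags win, and every run
logs seed, version and input checksums to standard error.

## Known limitations

- Annotation is consumed, never produced: no automatic speech-act
  classification, no audio/prosody, no CHAT/ELAN import.
- The forecaster is a deliberately minimal single-layer recurrence; it is
  an analysis instrument for one interaction's dynamics, not a general
  sequence model, and is trained per dialogue.
- Occupancy matrices are numeric only; plotting is left to the caller.
- Published per-subject figures from clinical recordings are not
  reproducible here because the underlying transcripts are unreleased;
  all quantitative checks run on the printed worked example, the encoded
  group descriptions, the summary table, or synthetic data.
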