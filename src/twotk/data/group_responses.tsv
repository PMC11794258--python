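subject_id	group	subtask	level	clarification
sds1	SDS	basket	0	0
sds2	SDS	basket	0	0
sds3	SDS	basket	0	0
sds4	SDS	basket	0	0
sds5	SDS	basket	3	0
ctl1	control	basket	0	0
ctl2	control	basket	0	0
ctl3	control	basket	0	0
ctl4	control	basket	0	0
ctl5	control	basket	1	1
sds1	SDS	door	0	0
sds2	SDS	door	0	0
sds3	SDS	door	0	0
sds4	SDS	door	0	0
sds5	SDS	door	0	0
ctl1	control	door	0	0
ctl2	control	door	0	0
ctl3	control	door	0	0
ctl4	control	door	1	0
ctl5	control	door	2	1
sds1	SDS	syllogism	0	0
sds2	SDS	syllogism	0	0
sds3	SDS	syllogism	0	0
sds4	SDS	syllogism	0	0
sds5	SDS	syllogism	0	0
ctl1	control	syllogism	0	0
ctl2	control	syllogism	1	0
ctl3	control	syllogism	2	0
ctl4	control	syllogism	2	0
ctl5	control	syllogism	3	0
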