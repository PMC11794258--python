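dialogue_id	speaker	epsilon	content	act_type	x	y	delta_task	delta_interlocutor	decisive
monte_cristo	Faria	1	What was your life at that time?	DMK	1	1	1	0	1
monte_cristo	Edmond	2	I was going to become captain of the Pharaoh.	MK	1	2	1	1	1
monte_cristo	Edmond	3	I was going to marry a beautiful girl.	MK	2	2	1	1	1
monte_cristo	Faria	4	Was there anyone who had a vested interest in you not becoming captain of the Pharaoh?	DMK	1	3	1	0	1
monte_cristo	Edmond	5	[...] only one man [...]	MK	1	4	1	1	0
monte_cristo	Faria	6	What was his name?	DMK	1	5	1	0	0
monte_cristo	Edmond	7	Danglars	MK	1	6	1	1	1
monte_cristo	Faria	8	So... now tell me about this beautiful young lady...	DMK	2	3	1	0	1
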