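sample_id	cohort	group	batch
c0	X	case	b1
c1	X	case	b1
c2	X	case	b1
c3	X	case	b1
c4	X	case	b1
k0	X	control	b1
k1	X	control	b1
k2	X	control	b1
k3	X	control	b1
k4	X	control	b1
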