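sample_id	cohort	group	batch
s01	X	case	b1
s02	X	control	b1
s03	X	case	b1
s04	X	control	b1
s05	X	case	b1
s06	X	control	b1
s07	X	case	b1
s08	X	control	b1
s09	X	case	b1
s10	X	control	b1
s11	X	case	b2
s12	X	control	b2
s13	X	case	b2
s14	X	control	b2
s15	X	case	b2
s16	X	control	b2
s17	X	case	b2
s18	X	control	b2
s19	X	case	b2
s20	X	control	b2
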