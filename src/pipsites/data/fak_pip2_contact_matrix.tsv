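simulation	K191	K216	K218	R221	K222	R229	R508	R514	K515	K578	K621	K627	R640	K657	R665
I	7.8	8.6	18.2	1.3	20.6	17.4	7.3	4.8	19.0	27.7	22.3	35.6	18.9	5.4	10.4
II	4.1	5.9	12.2	1.9	7.3	4.8	27.8	11.2	13.1	37.8	53.1	39.4	16.5	6.9	11.0
III	11.0	7.3	23.4	10.5	21.7	16.6	0.0	3.5	22.6	35.4	15.7	48.0	19.5	6.4	10.5
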