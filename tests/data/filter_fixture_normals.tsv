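# Matched-normal observations for the 12-record filter fixture.
# pos 1006 has normal depth 9 (< 10); pos 1007 has one alt read; pos 1010 sits
# exactly at the depth-10 boundary; all others comfortably pass.
patient_id	chrom	pos	ref	alt	depth	alt_count
P1	1	1001	C	T	30	0
P1	1	1002	C	T	30	0
P1	1	1003	C	T	30	0
P1	1	1004	C	T	30	0
P1	1	1005	C	T	30	0
P1	1	1006	C	T	9	0
P1	1	1007	C	T	30	1
P1	1	1008	C	T	30	0
P1	1	1009	C	T	30	0
P1	1	1010	C	T	10	0
P1	1	1011	C	T	30	0
P1	1	1012	C	T	30	0
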