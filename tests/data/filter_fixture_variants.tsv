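# 12-record filter fixture: one record per variant key, patient P1, sample S1.
# Each of the eight filter rules is violated by exactly one record; four pass
# (one of them at every threshold boundary simultaneously).
patient_id	sample_id	chrom	pos	ref	alt	gene	effect	alt_count	depth	vaf	tlod	mmq	seqq	strandq	trinuc_context
P1	S1	1	1001	C	T	PASS_ALL	missense	30	100	0.3	30	65	50	40	ACA
P1	S1	1	1002	C	T	FAIL_TLOD	missense	30	100	0.3	9.9	65	50	40	ACA
P1	S1	1	1003	C	T	FAIL_MMQ	missense	30	100	0.3	30	59	50	40	ACA
P1	S1	1	1004	C	T	FAIL_SEQQ	missense	30	100	0.3	30	65	19	40	ACA
P1	S1	1	1005	C	T	FAIL_STRANDQ	missense	30	100	0.3	30	65	50	19.9	ACA
P1	S1	1	1006	C	T	FAIL_NORMAL_DEPTH	missense	30	100	0.3	30	65	50	40	ACA
P1	S1	1	1007	C	T	FAIL_NORMAL_ALT	missense	30	100	0.3	30	65	50	40	ACA
P1	S1	1	1008	C	T	FAIL_TUMOR_DEPTH	missense	6	19	0.3158	30	65	50	40	ACA
P1	S1	1	1009	C	T	FAIL_VAF	missense	4	100	0.04	30	65	50	40	ACA
P1	S1	1	1010	C	T	PASS_BOUNDARY	missense	1	20	0.05	10	60	20	20	ACA
P1	S1	1	1011	C	T	PASS_B	nonsense	15	60	0.25	30	65	50	40	ACA
P1	S1	1	1012	C	T	PASS_C	synonymous	10	50	0.2	30	65	50	40	ACA
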