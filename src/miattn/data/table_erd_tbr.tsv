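subject	attention_erd	attention_tbr	inattention_erd	inattention_tbr
S1	-2.0164	2.3812	-1.5252	2.3041
S2	-2.3600	2.3354	-1.6173	2.3956
S3	-3.4486	2.3867	-1.1518	2.3754
S4	-0.8000	2.7402	0.1548	2.7892
S5	-2.4723	2.4687	1.1942	2.5904
S6	-0.1843	2.4665	-0.8234	2.5572
S7	-1.1349	2.6942	0.6306	2.7405
S8	-0.8348	2.5445	0.5188	2.4922
S9	-0.0784	2.6741	-0.3884	2.7631
S10	0.7046	2.8144	0.5164	2.8642
S11	-2.1853	2.3856	-0.7518	2.4522
S12	-1.2965	2.5771	0.4769	2.6837
S13	-0.5537	2.6593	-0.2098	2.6508
S14	-1.9164	2.5884	-1.4405	2.4663
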