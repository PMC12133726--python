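subject	attention_erd	attention_ami	inattention_erd	inattention_ami
S1	-2.0164	-0.0573	-1.5252	-0.0703
S2	-2.3600	-0.0688	-1.6173	-0.0759
S3	-3.4486	-0.0974	-1.1518	-0.0694
S4	-0.8000	-0.0205	0.1548	0.0021
S5	-2.4723	-0.0613	1.1942	0.0804
S6	-0.1843	0.0274	-0.8234	-0.0154
S7	-1.1349	-0.0385	0.6306	0.0469
S8	-0.8348	-0.0231	0.5188	0.0365
S9	-0.0784	0.0157	-0.3884	-0.0046
S10	0.7046	0.0486	0.5164	0.0344
S11	-4.3186	-0.0986	0.6518	0.0476
S12	-3.1437	-0.0894	0.5769	0.0371
S13	-2.7763	-0.0653	0.5098	0.0342
S14	-1.9164	-0.0591	0.6209	0.0466
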