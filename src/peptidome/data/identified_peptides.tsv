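lm_mz	rm_mz	sequence	n_term_mod	charge	experimental_mh	protein_id	start	stop
1116	1115.60	RAHGQESAIF		2	1115.551	SCTM1_HUMAN	69	78
1670	1668.84	GSVIDQSRVLNLGPIT		2	1668.923	UROM_HUMAN	590	605
1727	1725.92	EEALPVSLSQGQPSRQ		2	1725.872	MEP1A_HUMAN	636	651
2192	2190.89	IMSEEDGDDDGGCDDYAEGR	acetyl	4	2190.765	GP162_HUMAN	344	363
2192	2190.89	AESQSPGTSMTPSSGSFPSAYD		5	2190.778	KPB1_HUMAN	1021	1042
2216	2215.39	FRSGSVIDQSRVLNLGPITR		4	2215.214	UROM_HUMAN	587	606
2528	2527.26	VKQADSGSSEEKQLYNKYPDAVA		4	2527.217	OSTP_HUMAN	19	41
2661	2659.44	DEAGSEADHEGTHSTKRGHAKSRPV		5	2659.252	FIBA_HUMAN	605	629
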