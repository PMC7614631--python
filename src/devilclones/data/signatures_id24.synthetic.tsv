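channel	ID1	ID2	ID7
ins_A_1	0.00000000	0.00000000	0.00000000
ins_A_2-4	0.00000000	0.00000000	0.02500000
ins_A_5+	0.50000000	0.00000000	0.00000000
ins_C_1	0.00000000	0.00000000	0.00000000
ins_C_2-4	0.00000000	0.00000000	0.00000000
ins_C_5+	0.00000000	0.00000000	0.00000000
ins_G_1	0.00000000	0.00000000	0.00000000
ins_G_2-4	0.00000000	0.00000000	0.00000000
ins_G_5+	0.00000000	0.00000000	0.00000000
ins_T_1	0.00000000	0.00000000	0.00000000
ins_T_2-4	0.00000000	0.00000000	0.02500000
ins_T_5+	0.50000000	0.00000000	0.00000000
del_A_1	0.00000000	0.00000000	0.05000000
del_A_2-4	0.00000000	0.00000000	0.22000000
del_A_5+	0.00000000	0.50000000	0.18000000
del_C_1	0.00000000	0.00000000	0.02500000
del_C_2-4	0.00000000	0.00000000	0.00000000
del_C_5+	0.00000000	0.00000000	0.00000000
del_G_1	0.00000000	0.00000000	0.02500000
del_G_2-4	0.00000000	0.00000000	0.00000000
del_G_5+	0.00000000	0.00000000	0.00000000
del_T_1	0.00000000	0.00000000	0.05000000
del_T_2-4	0.00000000	0.00000000	0.22000000
del_T_5+	0.00000000	0.50000000	0.18000000
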