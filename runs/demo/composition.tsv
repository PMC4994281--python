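animal_id	cross_type	breeds	paternal_breed
BC_g1_0	two_way	B,C	
BC_g1_1	two_way	B,C	
BC_g1_2	two_way	B,C	
BC_g1_4	two_way	B,C	
BC_g1_5	two_way	B,C	
BC_g1_8	two_way	B,C	
BC_g1_9	two_way	B,C	
BC_g1_10	two_way	B,C	
BC_g1_11	two_way	B,C	
BC_g1_12	two_way	B,C	
BC_g1_13	two_way	B,C	
BC_g1_15	two_way	B,C	
BC_g1_17	two_way	B,C	
BC_g1_19	two_way	B,C	
BC_g1_20	two_way	B,C	
BC_g1_21	two_way	B,C	
BC_g2_0	two_way	B,C	
BC_g2_1	two_way	B,C	
BC_g2_3	two_way	B,C	
BC_g2_5	two_way	B,C	
BC_g2_6	two_way	B,C	
BC_g2_7	two_way	B,C	
BC_g2_8	two_way	B,C	
BC_g2_9	two_way	B,C	
BC_g2_10	two_way	B,C	
BC_g2_11	two_way	B,C	
BC_g2_13	two_way	B,C	
BC_g2_14	two_way	B,C	
BC_g2_15	two_way	B,C	
BC_g2_16	two_way	B,C	
BC_g2_18	two_way	B,C	
BC_g2_19	two_way	B,C	
BC_g3_0	two_way	B,C	
BC_g3_2	two_way	B,C	
BC_g3_4	two_way	B,C	
BC_g3_5	two_way	B,C	
BC_g3_7	two_way	B,C	
BC_g3_8	two_way	B,C	
BC_g3_9	two_way	B,C	
BC_g3_10	two_way	B,C	
BC_g3_11	two_way	B,C	
BC_g3_13	two_way	B,C	
BC_g3_14	two_way	B,C	
BC_g3_15	two_way	B,C	
BC_g3_16	two_way	B,C	
BC_g3_17	two_way	B,C	
BC_g3_19	two_way	B,C	
BC_g3_20	two_way	B,C	
BC_g4_1	two_way	B,C	
BC_g4_2	two_way	B,C	
BC_g4_4	two_way	B,C	
BC_g4_5	two_way	B,C	
BC_g4_6	two_way	B,C	
BC_g4_7	two_way	B,C	
BC_g4_8	two_way	B,C	
BC_g4_10	two_way	B,C	
BC_g4_11	two_way	B,C	
BC_g4_12	two_way	B,C	
BC_g4_13	two_way	B,C	
BC_g4_15	two_way	B,C	
BC_g4_17	two_way	B,C	
BC_g4_18	two_way	B,C	
BC_g4_19	two_way	B,C	
BC_g4_21	two_way	B,C	
BC_g5_0	two_way	B,C	
BC_g5_2	two_way	B,C	
BC_g5_3	two_way	B,C	
BC_g5_4	two_way	B,C	
BC_g5_5	two_way	B,C	
BC_g5_7	two_way	B,C	
BC_g5_8	two_way	B,C	
BC_g5_9	two_way	B,C	
BC_g5_10	two_way	B,C	
BC_g5_11	two_way	B,C	
BC_g5_12	two_way	B,C	
BC_g5_13	two_way	B,C	
BC_g5_14	two_way	B,C	
BC_g5_15	two_way	B,C	
BC_g5_17	two_way	B,C	
BC_g5_19	two_way	B,C	
ABC_g1_0	three_way	B,C	A
ABC_g1_1	three_way	B,C	A
ABC_g1_2	three_way	B,C	A
ABC_g1_3	three_way	B,C	A
ABC_g1_4	three_way	B,C	A
ABC_g1_9	three_way	B,C	A
ABC_g1_10	three_way	B,C	A
ABC_g1_11	three_way	B,C	A
ABC_g1_12	three_way	B,C	A
ABC_g1_13	three_way	B,C	A
ABC_g1_15	three_way	B,C	A
ABC_g1_16	three_way	B,C	A
ABC_g1_18	three_way	B,C	A
ABC_g1_19	three_way	B,C	A
ABC_g1_20	three_way	B,C	A
ABC_g1_21	three_way	B,C	A
ABC_g2_0	three_way	B,C	A
ABC_g2_1	three_way	B,C	A
ABC_g2_2	three_way	B,C	A
ABC_g2_3	three_way	B,C	A
ABC_g2_4	three_way	B,C	A
ABC_g2_5	three_way	B,C	A
ABC_g2_7	three_way	B,C	A
ABC_g2_9	three_way	B,C	A
ABC_g2_10	three_way	B,C	A
ABC_g2_11	three_way	B,C	A
ABC_g2_12	three_way	B,C	A
ABC_g2_13	three_way	B,C	A
ABC_g2_16	three_way	B,C	A
ABC_g2_19	three_way	B,C	A
ABC_g2_20	three_way	B,C	A
ABC_g2_21	three_way	B,C	A
ABC_g3_0	three_way	B,C	A
ABC_g3_1	three_way	B,C	A
ABC_g3_3	three_way	B,C	A
ABC_g3_4	three_way	B,C	A
ABC_g3_5	three_way	B,C	A
ABC_g3_6	three_way	B,C	A
ABC_g3_8	three_way	B,C	A
ABC_g3_9	three_way	B,C	A
ABC_g3_10	three_way	B,C	A
ABC_g3_11	three_way	B,C	A
ABC_g3_12	three_way	B,C	A
ABC_g3_14	three_way	B,C	A
ABC_g3_15	three_way	B,C	A
ABC_g3_17	three_way	B,C	A
ABC_g3_18	three_way	B,C	A
ABC_g3_20	three_way	B,C	A
ABC_g4_0	three_way	B,C	A
ABC_g4_1	three_way	B,C	A
ABC_g4_2	three_way	B,C	A
ABC_g4_5	three_way	B,C	A
ABC_g4_7	three_way	B,C	A
ABC_g4_8	three_way	B,C	A
ABC_g4_9	three_way	B,C	A
ABC_g4_11	three_way	B,C	A
ABC_g4_12	three_way	B,C	A
ABC_g4_13	three_way	B,C	A
ABC_g4_14	three_way	B,C	A
ABC_g4_15	three_way	B,C	A
ABC_g4_16	three_way	B,C	A
ABC_g4_18	three_way	B,C	A
ABC_g4_19	three_way	B,C	A
ABC_g4_20	three_way	B,C	A
ABC_g5_1	three_way	B,C	A
ABC_g5_2	three_way	B,C	A
ABC_g5_4	three_way	B,C	A
ABC_g5_5	three_way	B,C	A
ABC_g5_6	three_way	B,C	A
ABC_g5_9	three_way	B,C	A
ABC_g5_11	three_way	B,C	A
ABC_g5_12	three_way	B,C	A
ABC_g5_13	three_way	B,C	A
ABC_g5_14	three_way	B,C	A
ABC_g5_15	three_way	B,C	A
ABC_g5_16	three_way	B,C	A
ABC_g5_17	three_way	B,C	A
ABC_g5_18	three_way	B,C	A
ABC_g5_19	three_way	B,C	A
ABC_g5_21	three_way	B,C	A
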