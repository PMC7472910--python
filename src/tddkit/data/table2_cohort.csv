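patient,acute_r_hand,acute_l_hand,acute_r_foot,acute_l_foot,m3_r_hand,m3_l_hand,m3_r_foot,m3_l_foot,lesion,side_diff
1,-0.24,0.41,-0.06,0.50,0.08,0.08,0.00,0.45,"Right WM",
2,0.44,0.48,1.09,0.78,0.34,0.16,0.86,-0.21,"Left IC",
3,2.86,-0.03,0.64,-0.36,3.73,-0.13,0.43,0.03,"Bilateral WM, BS, cerebellum",
4,-0.13,5.57,-0.02,1.14,-0.24,0.66,0.45,1.18,"Right IC, LN, internal capsule",
5,2.36,-0.13,-0.10,-0.14,2.29,-0.35,0.04,0.65,"Left occipital and frontal lobule, bilateral parietal",
6,0.16,-0.24,-0.40,-0.62,1.53,0.16,-0.15,-0.80,"Right thalamus, cerebellum, WM",m3_r_foot
7,-0.03,-0.35,-0.28,-0.21,-0.35,-0.35,0.14,0.34,"Right medulla oblongata",
8,-0.35,5.10,-0.75,0.87,-0.24,4.96,-0.60,0.64,"Right IC, DLPFC, S2 OP1",
9,0.44,1.71,0.23,0.47,-0.13,0.44,-0.68,0.29,"Right thalamus, WM",
10,-0.35,-0.35,0.11,0.20,0.05,-0.35,0.29,-0.01,"Right CN, putamen",
11,3.04,-0.35,1.23,-0.41,-0.35,-0.35,0.95,-0.08,"Left medulla oblongata",
12,-0.35,-0.35,-0.14,-0.28,-0.35,-0.35,-0.46,0.51,"Left S2 OP1, cerebellum",
13,-0.24,-0.24,-0.40,-0.20,-0.13,-0.35,0.26,-0.04,"Left BS (Pons)",
14,-0.24,-0.24,-0.14,0.09,-0.24,-0.35,-0.21,0.04,"Right IC, WM",
15,0.91,-0.13,-0.39,-0.50,-0.24,0.30,-0.06,-0.00,"Bilateral WM",
16,-0.35,-0.35,-0.32,-0.19,-0.17,-0.35,-0.39,0.16,"Right WM",
17,-0.24,0.44,0.17,-0.61,-0.13,-0.35,0.39,-0.23,"Left thalamus",
18,-0.24,1.06,0.10,-0.13,0.26,-0.24,-0.33,-0.04,"Right IC, DLPFC",
19,-0.24,-0.13,0.38,0.20,-0.24,-0.35,-0.25,0.21,"Right IC, S2 OP1",
20,-0.03,-0.21,-0.15,-0.50,-0.24,-0.35,-0.03,-0.40,"Right BS (Pons), bilateral IC, WM",acute_r_foot;m3_r_foot
21,-0.35,-0.13,-0.28,-0.82,-0.35,-0.35,-0.31,-0.49,"Left S2 OP1, bilateral WM",acute_r_foot;m3_r_foot
22,-0.13,-0.35,-0.54,-0.47,-0.24,-0.24,-0.44,-0.54,"Right BS",
23,-0.35,-0.35,-0.55,-0.70,-0.35,-0.35,-0.47,-0.70,"Left WM",
24,-0.35,-0.35,-0.55,-0.15,-0.35,-0.35,-0.10,-0.53,"Bilateral cerebellum",
25,-0.35,-0.35,-0.71,-0.71,-0.31,-0.35,-0.71,-0.66,"Right cerebellum",
26,0.41,1.60,-0.52,0.57,-0.35,-0.35,-0.23,-0.37,"Bilateral putamen, WM",
27,-0.35,-0.35,-0.47,-0.33,-0.35,-0.35,-0.54,-0.66,"Left occipital lobule",
28,0.26,0.37,0.10,0.68,-0.13,-0.35,-0.47,-0.16,"Left LN, CN, right putamen, internal capsule",
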