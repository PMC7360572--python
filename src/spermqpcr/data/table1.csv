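sample_id,litter_size,litter_size_se,concentration_ng_ul,ratio_260_280,dnase
boar01,14.15,0.79,41.25,1.74,untreated
boar02,13.44,0.68,153.97,1.86,untreated
boar03,13.30,0.95,75.89,1.74,untreated
boar04,13.15,0.79,140.45,1.87,untreated
boar05,13.14,0.55,146.45,1.87,untreated
boar06,13.10,0.99,88.29,1.83,untreated
boar07,12.90,1.06,152.45,1.85,untreated
boar08,12.82,0.80,25.81,1.70,untreated
boar09,12.79,0.94,109.57,1.79,untreated
boar10,12.75,1.28,197.57,1.82,untreated
boar11,12.67,0.72,255.65,1.83,untreated
boar12,12.65,0.64,29.33,1.77,untreated
boar13,12.54,0.75,58.93,1.83,untreated
boar14,12.40,1.72,93.89,1.82,untreated
boar15,12.38,0.85,33.89,1.58,untreated
boar16,12.25,0.77,83.89,1.82,untreated
boar17,12.08,0.51,108.29,1.80,untreated
boar18,11.81,0.71,54.45,1.80,untreated
boar19,11.75,1.16,128.37,1.85,untreated
boar20,11.35,0.92,56.37,1.78,untreated
boar01,14.15,0.79,67.72,1.86,treated
boar02,13.44,0.68,35.80,1.79,treated
boar03,13.30,0.95,74.12,1.93,treated
boar04,13.15,0.79,123.00,1.85,treated
boar05,13.14,0.55,58.04,1.86,treated
boar06,13.10,0.99,17.00,1.54,treated
boar07,12.90,1.06,28.12,1.81,treated
boar08,12.82,0.80,129.56,1.93,treated
boar09,12.79,0.94,96.12,1.91,treated
boar10,12.75,1.28,21.40,1.89,treated
boar11,12.67,0.72,13.40,1.61,treated
boar12,12.65,0.64,21.08,1.84,treated
boar13,12.54,0.75,42.84,1.84,treated
boar14,12.40,1.72,33.64,1.88,treated
boar15,12.38,0.85,10.12,1.80,treated
boar16,12.25,0.77,33.96,1.84,treated
boar17,12.08,0.51,37.32,1.77,treated
boar18,11.81,0.71,18.28,1.55,treated
boar19,11.75,1.16,13.64,1.55,treated
boar20,11.35,0.92,10.36,1.72,treated
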