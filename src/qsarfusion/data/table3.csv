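id,est_ic50_nM,energy_kcal_mol
NSC 136954,1.989,61.239
NSC 70804,1.682,58.967
NSC 158029,1.885,57.944
NSC 603427,1.87,56.963
NSC 57782,1.6855,56.54
NSC 16739,1.5385,56.342
NSC 720227,1.914,55.839
NSC 618702,1.862,55.196
NSC 195178,1.7015,51.351
NSC 653142,1.557,51.19
NSC 653143,1.577,50.055
NSC 32200,1.901,49.439
NSC 342015,1.6515,47.327
NSC 343685,1.7615,46.436
NSC 205750,1.875,45.542
NSC 96538,1.705,44.344
NSC 210455,1.7935,42.258
NSC 314654,1.947,42.082
NSC 179894,1.6135,41.707
NSC 91710,1.701,40.533
NSC 370907,1.8785,40.502
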