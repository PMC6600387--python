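receptor_type,n,best_scored_MOE,best_scored_GOLD,best_scored_CovDock,best_scored_ICM-Pro,best_sampled_MOE,best_sampled_GOLD,best_sampled_CovDock,best_sampled_ICM-Pro
Hydrolase,204,2.07,2.33,1.71,2.76,1.54,1.51,1.39,1.61
Transferase,83,1.8,2.24,1.3,1.34,1.34,1.46,1.06,1.24
Ligase,3,2.9,2.63,1.08,1.41,1.25,1.04,0.84,1.41
Lyase,1,0.96,1.23,1.24,1.34,0.9,1.17,1.19,1.34
Oxidoreductase,6,1.7,1.44,2.37,1.13,1.18,1.06,2.37,1.13
Isomerase,6,1.49,1.2,1.02,2.25,1.33,0.78,1.01,2.25
Transcription,18,2.38,6.15,2.15,3.42,1.6,3.03,1.71,2.1
Viral Protein,4,3.91,0.81,4.29,4.93,2.97,0.81,1.3,4.93
Metal binding protein,5,1.72,5.54,5.43,2.37,1.04,4.54,3,1.67
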