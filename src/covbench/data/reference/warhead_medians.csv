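reaction_type,warhead_class,n,best_scored_MOE,best_scored_GOLD,best_scored_CovDock,best_scored_ICM-Pro,best_sampled_MOE,best_sampled_GOLD,best_sampled_CovDock,best_sampled_ICM-Pro
Nucleophilic Addition by Cys,Nitrile(cys),42,2.26,1.1,1.27,3.74,1.6,0.91,1.24,1.56
Nucleophilic Addition by Cys,Alkene(cys),117,1.99,2.47,1.47,1.68,1.4,1.59,1.18,1.41
Nucleophilic Addition by Cys,Carbonyl(cys),25,2.27,2.12,2.05,3.72,1.5,1.77,1.33,1.52
Nucleophilic Addition by Cys,Alkyne,1,2.01,0.67,0.42,0.39,1.9,0.67,0.35,0.39
Nucleophilic Addition by Cys,Guanyl,2,1.78,1.46,0.81,1.37,1.4,0.98,0.81,1.37
Nucleophilic Substitution (cys),Halide,15,1.67,2.31,4.37,1.06,1.3,2.17,4.37,0.88
Nucleophilic Substitution (cys),Others,16,2.1,2.19,2.12,2.09,1.6,1.47,1.3,1.77
Ring Opening by Cys,Heterocyclic,17,1.71,1.74,1.87,4.88,1.4,1.48,1.33,4.72
Disulfide Formation,Sulfydryl,10,1.94,2.94,2.52,2.92,1.3,2.47,2.52,1.95
Nucleophilic Addition by Ser,Nitrile(ser),3,1.38,2.54,0.73,2.66,1.3,1.77,0.52,2.66
Nucleophilic Addition by Ser,Carbonyl(ser),29,1.61,3.54,3.1,2.03,1.3,1.58,1.4,1.36
Nucleophilic Addition by Ser,Boric acid,8,1.94,2.57,2.94,2.44,1.5,1.88,2.74,2.44
Nucleophilic Substitution by Ser,Phosphonyl,3,2.32,2.33,5.81,1.68,1.5,2.08,3.25,1.68
Ring Opening by Ser,Lactam,40,1.73,2.95,1.7,2.53,1.5,1.62,1.7,1.48
Ring Opening by Ser,Lactone,2,2.09,2.56,2.52,5.66,1.5,1.6,1.6,4.98
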