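outcome_type,comparison_type,location,scale,df,printed_median,printed_low,printed_high,n_mas,median_tol,median_flag
general,general,-3.44,2.59,5,0.03,0.0002,5.16,6492,0.005,ok
obstetric,pharm_vs_placebo,-4.13,2.34,5,0.016,0.0002,1.86,50,0.0005,ok
obstetric,pharm_vs_pharm,-4.40,2.31,5,0.012,0.0001,1.16,46,0.0005,ok
obstetric,nonpharm_vs_any,-3.99,2.11,5,0.019,0.0003,1.07,69,0.005,ok
resource_use,pharm_vs_placebo,-2.55,2.73,5,0.078,0.0004,21.3,78,0.0005,ok
resource_use,pharm_vs_pharm,-2.83,2.70,5,0.061,0.0003,11.9,48,0.005,scale_sign_typo
resource_use,nonpharm_vs_any,-2.41,2.57,5,0.089,0.0005,13.3,243,0.005,ok
structure,pharm_vs_placebo,-2.43,2.50,5,0.086,0.0007,12.9,110,0.005,ok
structure,pharm_vs_pharm,-2.70,2.46,5,0.070,0.0004,8.32,17,0.005,ok
structure,nonpharm_vs_any,-2.29,2.32,5,0.105,0.0009,10.6,45,0.005,ok
general_health,pharm_vs_placebo,-3.16,2.50,5,0.040,0.0003,7.02,631,0.005,ok
general_health,pharm_vs_pharm,-3.44,2.44,5,0.032,0.0002,4.28,212,0.0005,ok
general_health,nonpharm_vs_any,-3.02,2.27,5,0.050,0.0006,4.00,878,0.005,ok
signs_symptoms,pharm_vs_placebo,-3.00,2.50,5,0.048,0.0004,7.56,367,0.005,ok
signs_symptoms,pharm_vs_pharm,-3.27,2.47,5,0.038,0.0003,5.69,133,0.0005,ok
signs_symptoms,nonpharm_vs_any,-2.86,2.33,5,0.060,0.0006,5.49,428,0.005,ok
mental_health,pharm_vs_placebo,-2.99,2.16,5,0.049,0.0007,4.70,174,0.005,ok
mental_health,pharm_vs_pharm,-3.27,2.14,5,0.039,0.0005,3.02,75,0.005,ok
mental_health,nonpharm_vs_any,-3.85,1.93,5,0.058,0.001,2.58,280,,discrepant
biological_marker,pharm_vs_placebo,-3.41,2.83,5,0.033,0.0001,10.2,401,0.0005,ok
biological_marker,pharm_vs_pharm,-3.68,2.78,5,0.027,0.00001,4.95,165,0.005,ok
biological_marker,nonpharm_vs_any,-3.27,2.66,5,0.037,0.0002,7.33,417,0.005,ok
subjective,pharm_vs_placebo,-2.76,2.58,5,0.063,0.0003,12.0,61,0.0005,ok
subjective,pharm_vs_pharm,-3.03,2.59,5,0.049,0.0002,8.11,39,0.005,ok
subjective,nonpharm_vs_any,-2.62,2.41,5,0.074,0.0007,9.06,156,0.005,ok
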