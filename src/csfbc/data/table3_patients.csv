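# Maximum CSF pressures, measured ICP, and head-substructure volumes, hydrocephalus cohort (11 patients), values as printed.
# The experimental-ICP confidence-interval cells are flagged ci_misprint: the source prints both bounds
# equal to the mean (impossible for sd > 0); the correct n=10 interval is 2553.5 - 2723.5 Pa.
variable,unit,No.1,No.2,No.3,No.4,No.5,No.6,No.7,No.8,No.9,No.10,No.11,mean,sd,se,cv_percent,ci_lower,ci_upper,flags
max_pressure_SAS_BC_A_Pa,Pa,3730.1,3810.5,3730.4,3994.6,3720.2,3892.3,3540.0,3030.7,3066.4,3170.2,3830.3,3592.3,344.0,103.7,9.6,3361.2,3823.4,
max_pressure_SAS_BC_B_Pa,Pa,3145.2,3095.3,2920.7,3189.6,2976.5,2815.1,2898.0,2691.2,2716.5,2943.4,3717.7,3009.9,284.7,85.8,9.5,2818.7,3201.2,
max_pressure_SAS_BC_C_Pa,Pa,2559.0,2635.0,2416.0,2659.0,2415.0,2495.0,2400.0,2390.0,2405.0,2670.0,2637.0,2516.5,117.1,35.3,4.7,2437.8,2595.1,
experimental_ICP_SAS_Pa,Pa,2705.0,2795.0,2562.0,2798.0,2543.0,2641.0,2494.0,2524.0,2555.0,2768.0,NA,2638.5,118.8,37.6,4.5,2638.5,2638.5,ci_misprint
max_pressure_CA_BC_A_Pa,Pa,3700.2,3803.1,3718.9,3992.2,3713.4,3805.3,3532.0,2992.2,3054.1,3121.1,3825.2,3568.9,348.7,105.1,9.8,3334.6,3803.1,
max_pressure_CA_BC_B_Pa,Pa,3100.3,3050.2,2818.7,3147.6,2988.6,2830.5,2890.0,2682.3,2670.5,2942.4,3712.1,2984.8,287.3,86.6,9.6,2791.8,3177.9,
max_pressure_CA_BC_C_Pa,Pa,2538.1,2619.5,2408.2,2645.7,2406.5,2477.3,2386.0,2381.2,2390.7,2650.1,2635.3,2503.5,115.9,35.0,4.6,2425.6,2581.4,
ventricular_volume_ml,ml,287.1,286.6,286.3,301.5,278.7,270.1,273.0,268.2,270.3,298.8,277.1,281.6,11.5,3.5,4.1,273.9,289.3,
brain_volume_ml,ml,1108.2,1108.6,1092.7,1130.6,1096.1,1018.3,1010.0,1009.2,1009.5,1109.1,1096.2,1071.7,48.6,14.7,4.5,1039.0,1104.3,
sas_volume_ml,ml,110.1,114.0,108.1,113.1,109.3,106.7,103.5,102.0,101.0,114.8,109.8,108.4,4.7,1.4,4.4,105.2,111.6,
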