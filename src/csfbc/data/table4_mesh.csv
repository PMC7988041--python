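# Mesh-convergence study: maximum CSF pressures/velocities of all 11 patients on three grids, and fine-mesh element counts.
quantity,unit,grid,No.1,No.2,No.3,No.4,No.5,No.6,No.7,No.8,No.9,No.10,No.11
max_pressure_SAS_Pa,Pa,coarse,2594,2669,2450,2693,2457,2538,2434,2432,2441,2711,2670
max_pressure_SAS_Pa,Pa,medium,2567,2643,2423,2667,2421,2503,2407,2397,2413,2678,2645
max_pressure_SAS_Pa,Pa,fine,2559,2635,2416,2659,2415,2495,2400,2390,2405,2670,2637
max_pressure_CA_Pa,Pa,coarse,2571,2658,2443,2681,2439,2511,2420,2418,2422,2687,2670
max_pressure_CA_Pa,Pa,medium,2543,2627,2411,2653,2413,2484,2391,2389,2397,2657,2642
max_pressure_CA_Pa,Pa,fine,2538,2619,2408,2645,2406,2477,2386,2381,2390,2650,2635
max_velocity_CA_cm_s,cm/s,coarse,7.9,4.38,4.27,8.7,7.19,5.76,6.28,5.3,5.99,7.4,7.91
max_velocity_CA_cm_s,cm/s,medium,7.83,4.32,4.21,8.63,7.1,5.69,6.22,4.26,5.92,7.37,7.87
max_velocity_CA_cm_s,cm/s,fine,7.8,4.3,4.2,8.6,7.07,5.68,6.2,4.25,5.9,7.35,7.85
fine_mesh_elements_ventricles_sas,count,fine,1280569,1285432,1265957,1308952,1248592,1221508,1221508,1178956,1185963,1315024,1242859
fine_mesh_elements_brain,count,fine,778095,779958,778098,788954,780024,765892,761206,758326,759842,785651,779862
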