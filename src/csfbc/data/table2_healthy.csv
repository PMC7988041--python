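# Maximum CSF pressures and head-substructure volumes, healthy cohort (8 subjects), values as printed.
variable,unit,No.1,No.2,No.3,No.4,No.5,No.6,No.7,No.8,mean,sd,se,cv_percent,ci_lower,ci_upper,flags
max_pressure_SAS_BC_A_Pa,Pa,599.6,699.1,719.1,704.2,589.3,594.3,710,584.3,650.0,62.5,22.1,9.6,597.7,702.3,
max_pressure_SAS_BC_B_Pa,Pa,575.2,622.8,655.1,614.1,515.6,570.2,641.5,495.1,586.2,58.0,20.5,9.9,537.7,634.7,
max_pressure_SAS_BC_C_Pa,Pa,505.4,508.5,515.9,499.1,462.1,489.2,510.7,454.9,493.2,23.0,8.1,4.7,474.0,512.4,
max_pressure_CA_BC_A_Pa,Pa,565.3,640.3,701.2,665.1,570.3,580.6,703.1,557.8,623.0,61.8,21.9,9.9,571.3,674.7,
max_pressure_CA_BC_B_Pa,Pa,569.5,597.4,636.8,583.3,492.1,529.3,598.8,485.1,561.5,54.2,19.2,9.7,516.2,606.9,
max_pressure_CA_BC_C_Pa,Pa,481.2,502.4,508.3,494.1,453.1,481.3,503.2,449.4,484.1,22.6,8.0,4.7,465.3,503.0,
ventricular_volume_ml,ml,20.1,20.9,21.8,19.89,20.1,19.6,20.9,19.5,20.3,0.8,0.3,3.9,19.7,21.0,
brain_volume_ml,ml,1275.1,1343.2,1369.1,1338.1,1305.5,1259.2,1210.3,1275.1,1297.0,52.1,18.4,4.0,1253.4,1340.5,
sas_volume_ml,ml,100.5,109.4,111.1,105.8,101.9,113.1,103.5,101.5,105.9,4.8,1.7,4.5,101.8,109.9,
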