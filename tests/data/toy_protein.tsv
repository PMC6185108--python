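feature_id	C1	C2	C3	C4	M1	M2	M3	M4
p01	1458086.9	4619589.8	4280759.7	1005825.8	3217005.6	2656384.2	3176081.9	3466737.5
p02	1879967.7	4826078.8	2596280.2	3326453.8	3358517.8	1327502.3	778394.4	2351825.7
p03	3938135.4	4168498.0	3784951.6	1009422.3	4610096.9	4109164.6	4449611.1	2854868.7
p04	4620359.5	709935.1	636299.8	590970.1	1637459.1	1618564.0	1343765.0	3051751.2
p05	675436.3	3156745.4	1247050.2	3550431.7	594839.1	1897565.9	4722535.8	2922783.7
p06	4152143.3	3461117.4	3248378.5	1360637.1	3084776.4	678588.9	4107489.8	4820319.1
p07	4343040.8	728193.4	2023970.4	1931014.4	1007226.5	NA	4088561.8	1911746.6
p08	NA	1081120.7	3950866.2	NA	NA	NA	3374374.8	3242004.2
p09	NA	NA	NA	NA	NA	NA	NA	NA
p10	3457597.6	954945.4	2212631.4	1101745.3	3481008.0	NA	2195842.0	2172757.8
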