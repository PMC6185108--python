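feature_id	C1	C2	C3	C4	M1	M2	M3	M4
g01	2175.2	2773.9	2506.5	1295.5	1460.4	2721.8	811.6	2606.7
g02	2553.6	1829.5	1466.7	NA	1360.7	1779.2	1910.0	2017.7
g03	2990.1	2543.9	2168.8	2975.7	NA	NA	NA	NA
g04	878.5	1932.8	1825.7	NA	NA	NA	NA	NA
g05	NA	NA	NA	NA	1613.0	808.2	2626.1	1139.8
g06	NA	NA	NA	NA	2207.4	2431.9	1001.3	NA
g07	1917.1	2716.9	NA	NA	930.4	1652.8	1510.7	1130.4
g08	2595.9	1634.8	NA	NA	NA	NA	NA	NA
g09	NA	NA	NA	NA	2929.2	1273.0	NA	NA
g10	2723.0	NA	NA	NA	2878.9	NA	NA	NA
g11	1223.4	2841.4	2015.1	1197.2	2744.9	NA	NA	NA
g12	1704.1	1326.9	883.7	2727.7	1829.0	2004.8	NA	NA
g13	855.4	1618.8	866.8	NA	2927.7	2247.1	1742.1	NA
g14	NA	NA	NA	NA	NA	NA	NA	NA
g15	1132.3	2853.5	811.4	2456.6	2583.2	1100.9	1721.6	NA
g16	831.4	NA	NA	NA	2396.9	1298.1	1236.7	1598.9
g17	1194.7	1561.3	NA	NA	1548.1	1397.4	NA	NA
g18	2956.9	1934.1	1946.6	NA	2434.1	NA	NA	NA
g19	1705.6	2830.1	NA	NA	1942.9	2892.1	1352.2	NA
g20	2288.2	2377.6	2185.2	2937.4	1531.9	1676.2	1246.4	911.5
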