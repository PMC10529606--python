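id,sex_code,mass_kg,length_cm,postwean_d,deployment_d,fastloc_locations,argos_locations,trips
13682,1,54.0,110,29,69,552,1001,4
13711,1,60.0,111,30,124,1601,1868,3
13783,1,50.5,107,24,38,324,545,2
13785,1,58.5,113,25,75,1347,1217,1
13804,1,54.0,110,19,84,1269,1342,2
13805,1,56.5,110,24,78,597,838,2
13827,1,61.5,117,27,111,1408,1560,4
13829,1,53.0,111,26,11,117,188,0
13831,1,62.0,118,20,52,547,753,1
13843,1,46.5,110,16,83,867,1103,0
13871,1,47.0,111,12,54,463,547,6
13882,2,41.5,108,20,53,647,901,0
13915,2,54.0,108,30,17,205,277,1
13916,2,57.0,112,17,174,3047,2675,9
13922,2,57.0,110,22,76,561,944,2
13939,2,64.0,114,7,46,357,594,2
13949,2,55.5,110,26,149,1743,2056,7
13969,2,56.0,115,23,118,1377,1476,3
13978,2,51.0,112,22,138,2667,2052,9
13985,2,62.0,110,22,122,922,1173,10
13987,2,55.0,116,13,40,217,361,0
13988,2,55.0,113,19,31,278,346,1
14587,2,,110,,160,2213,1928,11
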