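condition,kvp,mean_energy_keV,chamber_mGy,vendor_mGy,vendor_pct_diff,ct_air_mGy,ct_air_pct_diff,megavoltage_mGy,megavoltage_pct_diff
1,80,45.4,31.8,30.4,4.4,30.8,3.2,30.5,4.2
2,80,47.9,28.1,26.6,5.6,27.9,0.8,27.5,2.1
3,120,51.7,29.8,26.3,11.7,28.6,4.0,28.2,5.4
4,120,54.7,28.7,24.5,14.6,27.5,4.0,27.9,2.7
5,120,55.3,34.1,28.4,16.7,32.6,4.3,32.3,5.1
6,140,58.1,33.7,26.5,21.5,31.7,5.9,32.0,5.0
7,140,58.7,34.2,27.4,19.9,32.5,4.9,32.2,5.9
8,120,59.5,36.3,29.4,18.9,36.4,0.2,36.6,0.9
9,120,60.7,27.1,23.0,15.2,29.0,6.9,28.6,5.5
10,140,63.2,34.1,27.1,20.7,35.4,3.9,35.5,4.1
11,140,64.9,32.1,25.5,20.7,34.3,6.8,34.3,6.9
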