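condition,phantom,position,kvp,scan_extent_mm,scan_type,mean_energy_keV
1,16 cm,center,80,40,axial,45.4
2,16 cm,surface,80,150,helical,47.9
3,32 cm,center,120,150,helical,51.7
4,32 cm,center,120,40,axial,54.7
5,16 cm,center,120,40,axial,55.3
6,16 cm,center,140,40,axial,58.1
7,32 cm,center,140,40,axial,58.7
8,32 cm,periphery,120,40,axial,59.5
9,32 cm,surface,120,150,helical,60.7
10,16 cm,surface,140,150,helical,63.2
11,16 cm,surface,140,40,axial,64.9
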