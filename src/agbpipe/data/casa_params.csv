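code,type,eps_max,ndvi_min,ndvi_max,fpar_min,fpar_max
1,alpine meadow,0.542,0.023,0.634,0.001,0.95
2,alpine steppe,0.542,0.023,0.634,0.001,0.95
3,temperate meadow steppe,0.542,0.023,0.634,0.001,0.95
4,temperate typical steppe,0.542,0.023,0.634,0.001,0.95
5,montane meadow,0.542,0.023,0.634,0.001,0.95
6,warm-temperate tussock and shrub-tussock,0.542,0.023,0.634,0.001,0.95
7,tropical tussock and shrub-tussock,0.542,0.023,0.634,0.001,0.95
8,temperate desert steppe,0.542,0.023,0.634,0.001,0.95
9,temperate meadow,0.542,0.023,0.634,0.001,0.95
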