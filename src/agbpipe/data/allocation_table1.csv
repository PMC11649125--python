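code,type,rs_ratio,c_a,c_b,proxy_for
1,alpine meadow,6.8,0.43,0.37,
2,alpine steppe,5.2,0.43,0.37,
3,temperate meadow steppe,5.3,0.43,0.37,
4,temperate typical steppe,5.3,0.43,0.37,
5,montane meadow,6.3,0.43,0.37,temperate meadow
6,warm-temperate tussock and shrub-tussock,1.6,0.43,0.37,tropical tussock and shrub-tussock
7,tropical tussock and shrub-tussock,1.6,0.43,0.37,
8,temperate desert steppe,6.7,0.43,0.37,
9,temperate meadow,6.3,0.43,0.37,
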