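taxon_id,weight,sensitive
taxon_000,0.82,True
taxon_001,0.34,False
taxon_002,0.78,True
taxon_003,0.15,False
taxon_004,0.16,False
taxon_005,0.82,True
taxon_006,0.44,False
taxon_007,0.71,True
taxon_008,0.33,False
taxon_009,0.65,True
taxon_010,0.85,True
taxon_011,0.64,True
taxon_012,0.47,False
taxon_013,0.26,False
taxon_014,0.7,True
taxon_015,0.45,False
taxon_016,0.65,True
taxon_017,0.83,True
taxon_018,0.51,False
taxon_020,0.82,True
taxon_021,0.57,True
taxon_022,0.69,True
taxon_023,0.61,True
taxon_024,0.98,True
taxon_025,0.39,False
taxon_029,0.67,True
taxon_031,0.98,True
taxon_032,0.42,False
taxon_033,0.56,True
taxon_034,0.74,True
taxon_035,0.23,False
taxon_036,0.21,False
taxon_037,0.11,False
taxon_038,0.35,False
taxon_039,0.61,True
taxon_042,0.45,False
taxon_043,0.36,False
taxon_044,0.56,True
taxon_045,0.84,True
taxon_046,0.77,True
taxon_047,0.83,True
taxon_048,0.15,False
taxon_049,0.71,True
taxon_050,0.78,True
taxon_051,0.48,False
taxon_052,0.4,False
taxon_053,0.91,True
taxon_054,0.56,True
taxon_055,0.86,True
taxon_056,0.46,False
taxon_058,0.83,True
taxon_059,0.56,True
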