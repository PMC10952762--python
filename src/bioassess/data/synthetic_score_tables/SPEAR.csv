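taxon_id,at_risk
taxon_000,False
taxon_001,False
taxon_002,True
taxon_003,False
taxon_004,False
taxon_005,False
taxon_007,False
taxon_008,True
taxon_009,True
taxon_010,False
taxon_011,False
taxon_012,True
taxon_013,False
taxon_014,False
taxon_015,True
taxon_016,False
taxon_017,True
taxon_018,False
taxon_019,True
taxon_020,True
taxon_021,False
taxon_022,True
taxon_023,False
taxon_024,True
taxon_025,False
taxon_026,True
taxon_028,True
taxon_029,True
taxon_030,False
taxon_031,True
taxon_033,True
taxon_034,True
taxon_035,False
taxon_036,False
taxon_038,True
taxon_039,False
taxon_040,True
taxon_041,False
taxon_042,False
taxon_043,False
taxon_044,True
taxon_045,True
taxon_046,True
taxon_047,True
taxon_048,False
taxon_049,True
taxon_051,False
taxon_052,False
taxon_053,False
taxon_054,False
taxon_055,True
taxon_056,False
taxon_058,False
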