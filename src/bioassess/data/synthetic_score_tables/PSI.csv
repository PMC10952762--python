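taxon_id,group
taxon_000,A
taxon_001,D
taxon_002,B
taxon_003,D
taxon_004,D
taxon_005,A
taxon_006,B
taxon_007,B
taxon_008,A
taxon_009,C
taxon_010,C
taxon_011,C
taxon_012,A
taxon_013,D
taxon_014,C
taxon_015,A
taxon_016,D
taxon_017,A
taxon_018,B
taxon_019,A
taxon_021,A
taxon_022,C
taxon_023,A
taxon_024,A
taxon_025,A
taxon_026,B
taxon_028,A
taxon_029,A
taxon_030,B
taxon_031,A
taxon_032,B
taxon_033,B
taxon_034,B
taxon_035,C
taxon_036,B
taxon_037,D
taxon_038,B
taxon_039,D
taxon_040,D
taxon_041,D
taxon_042,B
taxon_043,D
taxon_044,C
taxon_045,B
taxon_046,B
taxon_047,B
taxon_048,D
taxon_049,A
taxon_050,D
taxon_051,B
taxon_052,B
taxon_053,B
taxon_054,D
taxon_055,A
taxon_056,D
taxon_057,A
taxon_058,A
taxon_059,C
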