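taxon_id,flow_group
taxon_000,I
taxon_001,VI
taxon_002,III
taxon_003,III
taxon_004,V
taxon_006,V
taxon_007,II
taxon_008,I
taxon_009,II
taxon_010,II
taxon_011,V
taxon_012,II
taxon_013,VI
taxon_014,VI
taxon_015,I
taxon_016,V
taxon_019,I
taxon_020,VI
taxon_021,I
taxon_022,II
taxon_023,I
taxon_024,II
taxon_025,II
taxon_026,I
taxon_027,VI
taxon_028,I
taxon_029,I
taxon_030,II
taxon_031,IV
taxon_032,VI
taxon_033,I
taxon_035,IV
taxon_036,V
taxon_037,III
taxon_038,II
taxon_039,II
taxon_040,V
taxon_041,VI
taxon_042,III
taxon_043,II
taxon_044,II
taxon_045,I
taxon_046,I
taxon_047,I
taxon_048,II
taxon_049,II
taxon_050,V
taxon_051,IV
taxon_052,VI
taxon_053,II
taxon_054,V
taxon_055,IV
taxon_057,VI
taxon_058,III
taxon_059,V
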