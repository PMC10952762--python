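taxon_id,score
taxon_000,6.0
taxon_001,1.9
taxon_003,1.5
taxon_004,2.0
taxon_005,9.6
taxon_006,4.6
taxon_007,6.0
taxon_008,8.3
taxon_009,4.8
taxon_010,1.3
taxon_011,4.6
taxon_012,6.3
taxon_013,1.1
taxon_014,1.6
taxon_015,3.7
taxon_016,4.8
taxon_017,6.9
taxon_018,4.8
taxon_019,9.2
taxon_020,5.4
taxon_021,8.7
taxon_022,8.8
taxon_023,4.1
taxon_024,9.6
taxon_025,9.4
taxon_026,7.8
taxon_027,1.0
taxon_028,7.5
taxon_029,8.2
taxon_030,4.5
taxon_031,6.6
taxon_032,4.6
taxon_033,8.4
taxon_034,3.0
taxon_036,2.9
taxon_037,1.3
taxon_039,9.5
taxon_040,4.2
taxon_041,1.3
taxon_042,1.8
taxon_043,1.9
taxon_044,7.4
taxon_045,4.3
taxon_046,7.8
taxon_047,8.3
taxon_051,4.7
taxon_053,3.1
taxon_054,1.9
taxon_055,8.8
taxon_056,4.5
taxon_057,5.6
taxon_058,1.8
taxon_059,3.0
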