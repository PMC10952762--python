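taxon_id,ofsi,tofsi
taxon_000,6.75,5.57
taxon_001,0.44,0.34
taxon_002,7.06,7.31
taxon_003,3.56,4.0
taxon_004,0.05,0.0
taxon_005,6.37,7.67
taxon_006,1.69,1.41
taxon_007,1.44,1.15
taxon_008,8.73,8.61
taxon_009,6.65,6.31
taxon_010,6.08,6.89
taxon_011,8.94,7.4
taxon_012,5.43,6.11
taxon_013,0.24,0.0
taxon_014,8.74,9.4
taxon_015,6.68,5.9
taxon_016,4.41,5.89
taxon_017,8.46,6.66
taxon_018,8.59,8.97
taxon_019,7.82,7.99
taxon_020,9.69,8.73
taxon_021,4.93,5.09
taxon_022,0.55,1.28
taxon_023,3.3,4.99
taxon_024,9.92,10.0
taxon_026,3.46,4.49
taxon_028,8.39,8.44
taxon_029,8.88,8.29
taxon_030,6.87,5.8
taxon_031,8.99,8.93
taxon_032,3.82,3.27
taxon_033,4.8,6.11
taxon_034,7.84,7.86
taxon_035,0.61,0.1
taxon_036,7.16,7.05
taxon_037,4.9,5.92
taxon_039,7.63,9.0
taxon_041,1.36,0.0
taxon_042,7.71,8.09
taxon_043,6.73,6.36
taxon_044,8.96,9.44
taxon_045,7.75,8.2
taxon_047,9.6,10.0
taxon_048,0.16,0.24
taxon_049,6.26,6.99
taxon_051,1.18,0.85
taxon_052,6.07,7.21
taxon_053,2.08,2.56
taxon_054,6.24,7.21
taxon_055,8.38,8.02
taxon_056,5.6,5.2
taxon_058,5.48,6.76
taxon_059,7.42,7.08
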