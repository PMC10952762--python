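taxon_id,s1,s2,s3,s4
taxon_000,7.74,8.04,8.34,8.64
taxon_001,2.15,1.71,1.26,0.82
taxon_002,6.21,6.31,6.4,6.5
taxon_003,2.66,2.28,1.9,1.52
taxon_005,7.48,7.74,8.01,8.27
taxon_006,7.74,8.04,8.34,8.64
taxon_008,6.48,6.61,6.74,6.87
taxon_009,5.19,5.15,5.11,5.07
taxon_010,3.38,3.1,2.81,2.53
taxon_011,6.73,6.89,7.06,7.22
taxon_012,2.71,2.33,1.96,1.59
taxon_013,3.44,3.16,2.89,2.61
taxon_014,6.76,6.93,7.1,7.27
taxon_016,8.07,8.41,8.75,9.09
taxon_017,8.77,9.21,9.64,10.08
taxon_018,6.72,6.88,7.05,7.21
taxon_019,8.57,8.97,9.38,9.79
taxon_020,7.26,7.5,7.73,7.97
taxon_021,7.18,7.4,7.62,7.85
taxon_022,2.97,2.64,2.3,1.96
taxon_023,5.77,5.81,5.84,5.88
taxon_024,7.99,8.33,8.66,8.99
taxon_026,7.52,7.79,8.06,8.33
taxon_027,1.77,1.27,0.77,0.27
taxon_028,9.2,9.7,10.19,10.68
taxon_029,7.94,8.26,8.59,8.91
taxon_030,8.24,8.61,8.97,9.34
taxon_031,9.06,9.53,10.01,10.48
taxon_032,5.44,5.43,5.42,5.41
taxon_033,5.42,5.4,5.39,5.38
taxon_034,7.95,8.28,8.61,8.93
taxon_035,6.26,6.37,6.47,6.57
taxon_036,2.16,1.71,1.26,0.82
taxon_037,2.46,2.06,1.65,1.24
taxon_038,3.55,3.28,3.02,2.76
taxon_039,8.92,9.37,9.83,10.28
taxon_040,6.3,6.41,6.51,6.62
taxon_041,3.3,3.0,2.71,2.42
taxon_042,3.47,3.2,2.93,2.66
taxon_043,2.9,2.55,2.2,1.86
taxon_044,7.99,8.32,8.66,8.99
taxon_045,3.81,3.59,3.37,3.14
taxon_046,8.01,8.34,8.68,9.01
taxon_047,5.73,5.77,5.8,5.83
taxon_048,2.74,2.37,2.0,1.64
taxon_049,7.39,7.64,7.89,8.15
taxon_050,7.35,7.6,7.85,8.09
taxon_051,8.39,8.78,9.16,9.55
taxon_052,3.3,3.01,2.72,2.43
taxon_053,6.7,6.86,7.03,7.19
taxon_054,6.91,7.09,7.28,7.47
taxon_055,3.64,3.39,3.15,2.9
taxon_056,5.6,5.61,5.62,5.63
taxon_057,4.46,4.32,4.18,4.05
taxon_058,6.13,6.21,6.3,6.38
taxon_059,5.69,5.72,5.74,5.77
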