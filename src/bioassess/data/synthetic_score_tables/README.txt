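SYNTHETIC score tables over an invented 60-taxon pool, generated
deterministically by bioassess.simulate.generate_score_table_fixtures
(pool_size=60, seed=0). They carry the structure of the real index
tables (WHPT class scores, LIFE flow groups, PSI sensitivity groups,
ePSI weights, CoFSI sub-index scores, TRPI scores, SPEAR at-risk
flags) but none of the published values. Replace these files with
published tables to score real samples.
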