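name	value	note
shared_state_energy_above_rss_kJmol	11	reactive-state energy of [↑↓↑↓ ↓↑↑↓] above the [↑↑↓↓ ↓↑↑↓] ground state, computed with the second-lowest auxiliary pattern; input to the missing-state estimate
missing_state_estimate_reported_kJmol	8	reported rough estimate for the unconverged [↓↓↑↑ ↓↑↑↓] reactive state above the ground state (additive decomposition gives 11 - 2.1 = 8.9; not forced to agree)
s3_attack_barrier_concluding_kJmol	30	S3-ion attack barrier as stated in the concluding summary; the results section gives 34 for mechanism 2 and the reference state of the 30 is ambiguous; neither value is forced to agree
cluster_separation_A	12	approximate centroid separation of the main and auxiliary clusters used by the synthetic active-site fixture
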