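"""Differential editing between groups under the modelled study design.

Uses the fast count-level simulator at the default study conditions
(8 controls at editing fraction 0.85, 16 cases at 0.79, coverage ~2000,
1% sequencing error, 50 unedited miRNAs), then runs the Welch t-test with
Benjamini-Hochberg FDR across the retained sites.
"""

import miredit as m

cfg = m.SimConfig(rng_seed=7)
counts, truth = m.simulate_position_counts(cfg)
sites, _ = m.call_sites(counts)
matrix = m.build_matrix(sites, cfg.design)
results = m.differential_editing(matrix, cfg.design, alpha=0.05)

print(f"{len(matrix.sites)} site(s) retained out of "
      f"{cfg.n_hairpins} simulated miRNAs\n")
cols = ["site", "mean_control", "mean_case", "welch_t", "welch_df", "p_raw",
        "p_bh", "significant"]
print(results[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))

# mean_control/mean_case recover the planted 0.85/0.79 editing fractions
# (shifted slightly toward 0.5 by the 1% error channel); the planted site
# is the only one surviving the filters and is BH-significant.
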