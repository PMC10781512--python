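# miredit

Detection and differential analysis of A-to-I editing in mature miRNAs
from small RNA-seq, with quantification of how a seed edit switches the
canonical target pool.

ADAR enzymes deaminate adenosine to inosine, which sequencers read as
guanosine, so miRNA editing appears as A→G mismatches in reads aligned to
their hairpin precursors. When the edit falls inside the seed (positions
2–8), it rewrites the miRNA's target-site vocabulary: the brain-enriched
miR-376a-3p, edited at mature position +6, is the flagship example. This
package is for researchers who want to call such editing sites from small
RNA-seq, test whether editing levels differ between two groups (e.g.
patients vs controls), and ask what a seed edit does to the target pool —
all on data they supply, or on a built-in synthetic cohort generator used
for validation throughout.

## The method

Per sample, reads are trimmed, aligned ungapped to the hairpin reference
(≤ 2 mismatches, best placement; multi-hairpin ties discarded), assigned
to a mature arm and tallied per mature position. At each reference
adenosine the **editing level** is

```
level = k / n
```

with `k` the reads carrying G and `n` the reads covering the position. A
site is retained when

1. Σ<sub>samples</sub> k ≥ 10 edited reads;
2. P(X ≥ k) < α<sub>err</sub> for X ~ Binomial(n, p=0.01) in at least one
   sample (the sequencing-error filter; p is the per-base error rate);
3. the mean level across samples is ≥ 10% (low-level editing is unlikely
   to be biologically meaningful).

Group differences are tested per site with the unpaired two-tailed Welch
t-test and controlled across sites by Benjamini–Hochberg FDR (α = 0.05).
Companion utilities: edited-vs-total abundance regression with residual
diagnostics, median-of-ratios (DESeq2-style) size factors, Spearman
correlation, trinucleotide (X-A-Z) context tabulation of edited
adenosines, and a canonical-site scanner that matches 8mer, 7mer-m8 and
7mer-A1 sites of the edited and non-edited seeds in a 3'UTR set and
compares the two target pools.

## Worked example

Differential editing at the default study conditions — 8 controls with a
planted editing fraction of 0.85 vs 16 cases at 0.79 at mature position
+6 of one miRNA among 50 unedited ones, coverage ~2000, 1% sequencing
error:

```python
import miredit as m

cfg = m.SimConfig(rng_seed=7)
counts, truth = m.simulate_position_counts(cfg)
sites, _ = m.call_sites(counts)
matrix = m.build_matrix(sites, cfg.design)
print(m.differential_editing(matrix, cfg.design, alpha=0.05))
```

prints (see `examples/02_differential_editing.py`):

```
            site  mean_control  mean_case  welch_t  welch_df     p_raw      p_bh  significant
sim-mir-001-3p:6        0.8444     0.7847    -13.6     15.32 5.871e-10 5.871e-10         True
```

The single planted site is the only one surviving the filters; the group
means recover the planted fractions (drawn slightly toward 0.5 by the 1%
error channel) and the 6-point editing gap is highly significant.

The seed-edit target switch (`examples/03_target_pool_switch.py`):

```
non-edited mature: AUCAUAGAGGAAAAUCCACGU  seed=UCAUAGA
edited mature:     AUCAUGGAGGAAAAUCCACGU  seed=UCAUGGA
scanned 500 random UTRs:
  non-edited targets: 70
  edited targets:     72
  shared:             7 (5.2% of the union)
```

One seed base change makes the site vocabularies nearly disjoint: only a
few percent of targets are shared between the isomiRs.

Each script in `examples/` demonstrates one capability (read-level site
calling, differential testing, target-pool comparison, motif context,
full pipeline). A thin CLI wraps the same calls
(`miredit simulate|align|call-sites|diff-edit|correlate|target-switch|motif|run`).

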