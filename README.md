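# hrsip

High-resolution DNA stable isotope probing (HR-SIP) analysis for soil
microbiome experiments.

DNA-SIP identifies microorganisms that assimilate a specific carbon source:
soil receives an amendment in which one substrate (here xylose or cellulose)
is ¹³C-labeled, DNA is separated on CsCl density gradients, and taxa whose
DNA shifted to higher buoyant density must have incorporated the label. In
the high-resolution variant, SSU rRNA gene amplicons are sequenced from ~20
fractions of every gradient, and each ¹³C gradient is compared against a
paired unlabeled control gradient fraction-by-fraction. `hrsip` implements
the downstream statistics for such experiments, for microbial ecologists who
have OTU count tables per gradient fraction and want defensible calls about
who ate what, when.

## What it computes

- **Responders** — OTUs enriched in the heavy fractions
  (ρ ∈ [1.7125, 1.755] g/mL) of a ¹³C gradient relative to control, per
  substrate × day. The test is a gamma-Poisson (negative binomial) GLM on
  fraction counts: for OTU *i*,
  `K_ij ~ NB(mean = s_j * 2^(β₀ + β₁ x_j), dispersion α_i)` with x_j the
  labeled-treatment indicator, so β₁ is the log₂ fold change (LFC). A
  one-sided Wald test uses the data-derived null
  `H₀: LFC ≤ mean(LFC) + sd(LFC)` over all tested OTUs, after a sparsity
  filter (present in ≥ 45% of the comparison's heavy fractions) and with
  Benjamini–Hochberg control at FDR 10%.
- **ΔBD** — each OTU's abundance-weighted buoyant-density center of mass,
  interpolated at 20 evenly spaced densities over the range shared by both
  gradients; the labeled-minus-control difference is a qualitative measure
  of the degree of labeling.
- **Temporal trends** — NB regression of non-fractionated (bulk) community
  counts on sampling day as an ordered factor (orthogonal polynomial
  contrasts; two-sided Wald on the linear term), per OTU or per taxonomic
  class.
- **Phylogenetic structure** of responder sets — weighted UniFrac between
  fraction communities, NRI/NTI clustering z-scores against permutation
  nulls, and consenTRAIT clade depth (τ_D).
- **Synthetic gradients** — a generative simulator (GC-driven density
  centers, isotope shifts, compositional Dirichlet-multinomial counts) with
  per-OTU ground truth, so the whole pipeline is testable without
  sequencing data.

See `docs/methods.md` for the model details and assumptions.

## Worked example

```python
from hrsip import (SimConfig, simulate_gradient_pair, ComparisonSpec,
                   detect_responders, delta_bd)

cfg = SimConfig(n_otus=100, n_labeled=10, depth=30_000, max_shift=0.03, seed=7)
counts, meta, truth = simulate_gradient_pair(cfg, day=3, substrate="13C-cellulose")

spec = ComparisonSpec("13C-cellulose", 3, "13C-cellulose_d3", "control_d3")
res = detect_responders(counts, meta, spec)
hits = res[res.responder]
print(f"tested {int(res.passed_sparsity.sum())} of {len(res)} OTUs, "
      f"{len(hits)} responders")
print(hits[["otu_id", "lfc", "se", "p_adj"]].round(3).to_string(index=False))

dbd = delta_bd(counts, meta, "13C-cellulose_d3", "control_d3",
               otu_ids=list(hits.otu_id))
print("mean responder delta BD: %.4f g/mL" % dbd.delta_bd.mean())
```

Output:

```
tested 91 of 100 OTUs, 8 responders
otu_id   lfc    se  p_adj
OTU.19 8.166 1.573  0.018
OTU.30 6.614 1.015  0.014
OTU.50 7.542 1.315  0.014
OTU.51 7.296 1.380  0.026
OTU.68 7.084 1.082  0.014
OTU.76 6.188 0.961  0.023
OTU.78 7.113 1.166  0.014
OTU.95 8.802 1.373  0.004
mean responder delta BD: 0.0333 g/mL
```

Nine OTUs were removed by the sparsity filter; the 8 responders (all truly
labeled in this simulation — `truth["labeled"]` holds the ground truth) show
LFCs of 6–9 log₂ units in the heavy fractions, and their mean density shift
of 0.033 g/mL approaches the simulated full-labeling shift of 0.03 g/mL plus
compositional distortion. Two truly labeled OTUs fall short of the FDR
cutoff — the data-derived threshold is deliberately conservative.

The same workflow is scriptable from the shell:

```bash
hrsip simulate --out data --seed 7
hrsip detect   --counts data/gradient_counts.tsv \
               --metadata data/gradient_metadata.tsv --out results
hrsip temporal --counts data/timecourse_counts.tsv \
               --metadata data/timecourse_metadata.tsv --out results
hrsip phylo    --tree tree.nwk --positive-tips responders.txt --out results
```

Every run writes `run_log.yaml` (version, seed, effective configuration) to
its output directory; configuration is a flat YAML of dotted keys (e.g.
`responders.fdr: 0.10`, `density.heavy_lo: 1.7125`).

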