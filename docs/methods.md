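# Methods

## The problem

DNA stable isotope probing (SIP) identifies which microorganisms assimilate
a specific carbon source: soil is amended with a ¹³C-labeled substrate, DNA
is extracted and separated on a CsCl density gradient, and taxa whose DNA
became heavier than expected must have incorporated the label. The
high-resolution variant (HR-SIP) sequences SSU rRNA gene amplicons from
~20 fractions of every gradient and compares labeled against unlabeled
control gradients fraction-by-fraction, which allows detection of partial
labeling against the confounding natural density variation caused by genome
G+C content. This package implements the full downstream analysis:
responder detection, degree-of-labeling estimation (ΔBD), community
time-course modeling, and phylogenetic characterization of responder sets,
plus a generative simulator that provides ground truth for every stage.

## Physical layer (`hrsip.density`)

Buoyant density is obtained from refractometry as ρ = aη − b with
a = 10.9276 and b = 13.593 g/mL (CsCl, 20 °C), after correcting the
measured refractive index for the gradient buffer:
η_corrected = η_observed − (η_buffer − 1.3333). "Heavy" (high-density)
fractions are those with ρ in the closed window [1.7125, 1.755] g/mL, where
¹³C-labeled DNA concentrates. The window is treated as closed because the
data are continuous and endpoint handling is immaterial; both window and
calibration coefficients are configurable.

## Responder detection (`hrsip.nb`, `hrsip.responders`)

For each (substrate, day) pair the heavy fractions of the labeled gradient
are contrasted with the corresponding control fractions under a
gamma-Poisson (negative binomial, NB) GLM with a log link, per-sample
offsets log(s_j), and design intercept + treatment indicator. Fractions
within a gradient are treated as independent replicates of their treatment
group — the only estimable reading when the design has one gradient per
treatment × day. The engine is self-contained:

- **Size factors.** Median-of-ratios against per-OTU geometric means,
  restricted to OTUs observed in all samples; with fewer than 10 such OTUs
  (common in sparse fraction data) a positive-counts variant is used.
  Factors are rescaled to geometric mean 1.
- **Dispersion.** Per-OTU α in Var = μ + αμ², initialized by method of
  moments on normalized counts within design cells and refined by maximum
  likelihood with fitted means, bounded to [1e-8, 10]; OTUs with fewer
  than two positive counts receive the 20%-trimmed mean of the remaining
  estimates. This replaces the trend + empirical-Bayes shrinkage of
  RNA-seq frameworks with a transparent, testable estimator; the inference
  downstream depends on LFC ranking and Wald SEs, not on the exact
  shrinkage rule.
- **Fitting.** Newton iterations with step halving on the penalized NB
  log-likelihood, coefficients on the log2 scale (LFC). A weak ridge
  (prior variance 36 log2², non-intercept terms only) keeps LFCs finite
  when a group is all zeros — which sparse fraction data routinely
  produce — at the cost of ~0.1% shrinkage on well-determined
  coefficients. SEs come from the observed information at the optimum.
- **Testing.** The null hypothesis is data-derived: an OTU responds only
  if its LFC exceeds the mean plus one sample (n−1) standard deviation of
  all tested OTUs' LFCs (one-sided Wald). OTUs are first filtered for
  sparsity: present (count > 0) in at least 45% of the comparison's pooled
  heavy fractions, boundary inclusive. Benjamini–Hochberg correction is
  applied over the tested OTUs at FDR 10%. The LFC pool for the threshold
  is the tested (sparsity-passing) set of that comparison; pooling across
  days is not done, and the choice is exposed in configuration.

A responder is an OTU with adjusted p < 0.10 in at least one comparison.
Aggregation reports per-substrate responder sets (union over days), first
day of response, per-day counts, and shared vs substrate-exclusive sets
(exclusive counts omit the shared set).

## Degree of labeling, ΔBD (`hrsip.deltabd`)

Per OTU and gradient, relative abundance is computed within the gradient's
fractions, restricted to the density range shared by the labeled/control
pair, linearly interpolated at 20 evenly spaced densities, and summarized
as the density-weighted average (center of mass). ΔBD is the labeled minus
control center of mass. ΔBD is a *qualitative* measure: because the counts
are compositional, an OTU's relative-abundance profile is its DNA mass
profile divided by the fraction-total profile, which attenuates or inflates
the recovered shift depending on where the rest of the community sits
(simulations with full labeling and a 0.036 g/mL true shift recover means
around 0.026–0.045 across seeds). Group means over responder sets remain
monotone in the true atom-fraction excess, which is the use the statistic
is designed for. OTUs with zero interpolated abundance in a gradient's
common range yield missing values, not zeros. No extrapolation outside the
observed fraction range is performed.

## Time-course model (`hrsip.temporal`)

Abundance dynamics use non-fractionated (bulk) samples. Sampling day is an
ordered factor: days are ranked (1, 3, 7, 14, 30 → 1…5) and expanded into
orthonormal polynomial contrasts; the NB GLM fits all contrasts but tests
only the linear term (two-sided Wald), because both increases and
decreases are reported. Higher-degree terms absorb non-monotone structure.
OTUs are filtered on base mean (mean normalized count ≥ 1) before BH
correction at FDR 10%; no outlier replacement is applied. Per-class
results aggregate counts at a taxonomic rank first (totals are conserved;
missing labels pool into an explicit "unclassified" bucket).

## Phylogenetic ecology (`hrsip.phylo`)

- **Weighted UniFrac** between fraction communities: Σ_b ℓ_b |A_b − B_b|
  over branches, with A_b, B_b the subtree proportion sums; the normalized
  form divides by Σ_b ℓ_b (A_b + B_b). Cross-checked in tests against
  scikit-bio's implementation.
- **NRI / NTI**: z-scores of mean pairwise (MPD) and mean nearest-taxon
  (MNTD) patristic distance of a tip set against a permutation null,
  negated so positive values mean clustering. The default null shuffles
  tip labels within a species pool; the independent-swap null (checkerboard
  swaps preserving row and column totals of a presence/absence community
  matrix) is provided for multi-community analyses — it degenerates when
  only a single responder set is analyzed, which is why label shuffling is
  the single-set default. z-scores use the sample sd over null draws. An
  exhaustive-enumeration oracle is included for small trees; note the ddof
  convention: enumerating all m same-size sets and using the sample sd
  (n−1, the convention of common ecophylogenetic software) differs from
  the population sd of the exact null by √(m/(m−1)), and the Monte-Carlo
  estimate converges to the latter. Both are available (`ddof` argument).
- **consenTRAIT** (τ_D): maximal clades in which ≥ 90% of tips carry the
  trait contribute the mean root-to-positive-tip distance; positive tips
  in no qualifying clade contribute half their terminal branch length
  (both the consensus level and the singleton rule are configurable). τ_D
  is the mean over clades; it scales linearly with branch lengths.

## Synthetic data (`hrsip.simulate`)

The generator emulates the study design: paired labeled/control gradients
per sampling day, 20 fractions evenly spaced on [1.67, 1.77] g/mL, plus a
replicated non-fractionated time course. Mechanism per OTU i:

- unlabeled center ρ_i = 1.660 + 0.098·GC_i (the standard linear
  GC–buoyant-density relation), GC_i ~ Beta(50, 50) — a soil-like
  community with unlabeled DNA at 1.709 ± 0.005 g/mL;
- labeling shifts the center by atom_excess × max_shift (default
  max_shift 0.036 g/mL, the full-labeling shift);
- DNA spreads around its center as a two-component Gaussian mixture: a
  narrow core (sd 0.004 g/mL) plus a small wide tail (5% of mass,
  sd 0.02 g/mL) representing diffusion and fragment-length smearing —
  without the tail component, strongly labeled OTUs vanish from
  control-gradient heavy fractions entirely and the 45% sparsity filter
  removes exactly the OTUs the method is meant to find, which real
  gradient profiles (broad-based, never truly zero) do not show;
- expected mass per fraction is the OTU's Gaussian-mixture mass in the
  fraction's density bin times its relative abundance (lognormal, σ = 1);
- sequencing is compositional at fixed depth per fraction (amplicon
  libraries are pooled equimolar): counts are Dirichlet-multinomial with
  concentration 300 on the fraction's mass-normalized proportions; a
  fraction with no DNA mass falls back to trace amplification of the bulk
  community profile.

What the simulator does **not** emulate: PCR/chimera artifacts, multiple
strains per OTU, cross-feeding dynamics, gradient-to-gradient density
calibration error, and per-fraction depth variation. Consequently, passing
recovery tests demonstrates the statistical pipeline is correct under the
stated mechanism, not that real data meet its assumptions.

A note on power under these conditions: with the narrow 0.004 g/mL core, an
OTU's counts vary by orders of magnitude across the ~8 heavy fractions per
gradient, so treating fractions as replicates inflates the NB dispersion
(α ≈ 1–5) and Wald SEs (≈ 1–1.6 log2). Detection at shift 0.03 g/mL and
depth 30,000 recovers most but not always all of 10 labeled OTUs among 100
(typically 5–9, essentially zero false positives); an RNA-seq reference
framework run on the same simulated comparisons shows the same ceiling, so
this reflects the data conditions, not the estimator. The data-derived
mean + sd threshold makes the test conservative — null simulations yield
responder-call rates far below the nominal 10% FDR.

## Numerical choices and degenerate inputs

- Tied fraction densities within a gradient are averaged before
  interpolation (interpolation needs strictly increasing knots).
- Center of mass with all-zero weights is undefined and returns NaN with a
  warning rather than 0, to avoid biasing group means.
- GLM non-convergence after 100 Newton iterations flags the OTU and
  excludes it from testing.
- Dispersion optimization is on log α with scipy's bounded scalar
  minimizer; the Poisson limit is used below α = 1e-12.
- BH adjustment delegates to statsmodels (`fdr_bh`), with input
  validation.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  configuration; identical seeds give bit-identical outputs.

## Problem sizes

Simulation-based tests and the acceptance script use communities of
50–100 OTUs, 20 fractions per gradient at depths 10,000–50,000 reads, 25
null-simulation seeds for responder error control and 20 for the
time-course null — sizes at which every recovery statistic is stable while
the full suite runs in well under the budget of an interactive session.

## Known limitations

- One gradient per treatment × day means biological replication is absent
  by design; the GLM's replicates are fractions, and dispersion therefore
  conflates density-profile shape with sampling noise (see power note).
- ΔBD is compositional and qualitative; it is not an atom-fraction-excess
  estimator and is not used for responder identification.
- rrn copy-number inference by phylogenetic placement, NMDS ordination and
  permutational MANOVA are out of scope; the weighted UniFrac matrix can
  be fed to any external ordination tool.
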