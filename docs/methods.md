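# Methods

This note documents the models and procedures implemented in `rnplc`, the
assumptions behind them, the parameters that matter, and the design choices
made where conventions were genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Experimental design being modeled

The pipeline targets an RNase-coupled AP-MS study of RNA-binding proteins:
each bait RBP is immunopurified in triplicate with and without RNase
treatment, multiplexed into one TMT11 mix per bait (channel 126 carries a
pooled spike-in; three +RNase IPs, three −RNase IPs, and two IgG controls
per condition fill the remaining ten channels), and quantified at the
protein-group level. An orthogonal SEC-MS experiment fractionates native
lysate (fractions 10–66) so that complex members co-elute at a
mass-calibrated apex. Comparing which preys survive the two RNase
conditions classifies every interaction's RNA dependency.

## Normalization chain (tmt)

Order is fixed and tracked by stage flags: MS1 apportioning → ppm →
batch correction → z-scoring. Each stage refuses to run twice or out of
order.

* **MS1 apportioning.** The per-protein, per-mix Top3-MS1 quantity is
  distributed over the mix's reporter channels proportionally to reporter
  intensities. The exact arithmetic of MS1-based correction is not a
  community standard; proportional apportioning is this package's choice.
  It preserves within-mix channel ratios exactly, conserves the Top3 total
  (tested to 1e-9), and leaves all-zero reporter rows missing.
* **ppm + log2.** Each sample column is scaled to sum to 1e6 over observed
  proteins, then log2(x+1). Missing values stay missing; nothing is imputed
  anywhere in the pipeline.
* **Batch correction.** Within a mix, each non-spike sample is corrected by
  the protein-wise mean of the other non-spike samples; the spike-in is
  corrected by the mean of everything else (it pools both conditions, so no
  condition-matched subset exists for it). Means exclude missing values.
  Note the deliberate consequence: enrichment shared by many channels of a
  mix is partially absorbed into the subtracted mean, so a direct
  interactor (enriched in 6 of 10 channels) retains a smaller corrected
  signal than a condition-specific one. The quality-control and calling
  thresholds below operate on this attenuated scale.
* **z-scoring.** Per sample across proteins, sample standard deviation
  (n−1). Constant columns become zeros and are flagged. The z > 1.645
  enrichment rule ("top 5%") only makes sense within a sample's
  distribution, which is why z-scoring is per sample, not per protein.

**Failed-IP detection.** A bait × condition IP set fails when the bait's z
exceeds 1.645 in fewer than two usable replicates, when the bait is
unmeasured, or when fewer than two replicates survive a sparsity filter
(replicates quantifying < 50% of the mix-median protein count are dropped;
the 50% is configurable since no standard value exists). Failed IP samples
are not discarded: they join the IgG controls in the background pool of
their RNase condition.

## HCIP calling and classification (hcip)

A prey passes for a bait × condition when all three hold: z > 1.645 in ≥ 2
replicates (strict inequalities throughout — the thresholds are written as
">"), log2 ratio of medians (prey replicates vs pooled background) > 1, and
one-sided Wilcoxon rank-sum p < α. The rank-sum test is exact when both
groups have ≤ 25 observations and no cross-group ties, and uses the normal
approximation with continuity correction otherwise; an all-tied degenerate
input returns p = 1 rather than an error. α defaults to 0.05 with a
per-bait 0.01 override available (the criterion for switching a bait to the
stricter level is a user decision, exposed as configuration).

The background pool spans all mixes of a condition. Pooling across mixes
maximizes background sample size (important for a 3-vs-n rank-sum test) at
the cost of assuming exchangeable backgrounds across mixes, which holds
after per-sample z-scoring.

Classification is a total, single-valued function per bait: called in both
conditions → direct; only −RNase → RNA-mediated; only +RNase →
RNA-shielded; bait QC-failed in exactly one condition → all its called
preys undetermined; failed in both → the bait is dropped.

## SEC co-elution (sec)

A deliberately compact caller restricted to a candidate pair list, not a
full complex-detection framework: replicate matrices are averaged cellwise
(missing values excluded from each mean), profiles are smoothed with a
centered 3-fraction moving average, and local maxima above a noise floor
(max of a configurable absolute floor and 2 × the profile median) are kept,
merging apexes closer than 3 fractions. A pair shares a peak when apexes
lie within Δ = 2 fractions; its score is the best Pearson correlation over
a ±5-fraction window centered between the apexes, requiring ≥ 3 mutually
observed fractions. Δ, the window, and the smoothing width have no
published values; the defaults here are fixed but configurable.

Significance is decoy-based: n ≥ 100 random co-measured pairs outside the
candidate set are scored identically, the empirical p-value is
(1 + #{decoy ≥ target})/(1 + n_decoys) (never zero by construction), and
Benjamini–Hochberg q-values are thresholded at 0.1. Decoy pairs without a
shared peak rank below every real score; candidate pairs without a shared
peak are never called.

## Network assembly and stoichiometry (network)

Edges are unordered pairs. When two baits report the same pair with
different classes, the pair keeps the strongest claim under the precedence
direct > mediated > shielded > undetermined and is flagged as conflicting
(conflicts are surfaced, not hidden; per-bait provenance is retained).
Merging with SEC calls collapses shared pairs into dual-support edges, so
|merged| = |IP| + |SEC| − |overlap| holds exactly. Reference PPI resources
annotate per-edge support flags; co-localization of an edge is *full* when
the two proteins' localization sets are identical, *partial* when they
intersect, *none* when disjoint, *unknown* when either is unannotated.

Interaction stoichiometry uses un-normalized intensities: log2(x+1),
replicate-averaged (mean of logs — the alternative, log of means, is not
used; the difference is a Jensen term that cancels in the prey−bait
contrast to first order), then stoichiometry_ip = log2 prey − log2 bait in
the bait's IP channels and stoichiometry_abundance the same contrast in the
replicate-averaged total proteome. Unmeasured proteins yield recorded
missing values.

## Resampling test (resampling)

F_exp = |edges ∩ reference| / |edges| on unordered pairs. The
degree-preserving null redraws, for each bait, its observed prey count
uniformly without replacement from the universe (a protein may serve
several baits, mirroring independent per-bait lists); the all-pairs mode
draws |edges| uniform pairs. p = (1 + #{F_i ≥ F_exp})/(1 + n). With the
tie-inclusive ≥ and the add-one correction this estimator is valid but
conservative (super-uniform) when F has ties, which is the correct
direction for a support test. n defaults to 1000, with larger values
available.

## Bridge scores (bridge)

σ_{s,t} and σ_{s,t|v} are computed by breadth-first layered counting (one
BFS per bait endpoint, σ_{s,t|v} = σ_s(v)·σ_t(v) on shortest-path nodes).
Conventions, where the formulas leave room:

* v is an *interior* node — contributions never count v ∈ {s, t}, matching
  standard betweenness.
* Unreachable (s, t) pairs contribute 0 but remain in the normalizer ("the
  total number of (s, t) pairs" is read literally); an exclude-unreachable
  option can be built from the returned normalizers.
* The graph is treated as simple and undirected; baits with several step
  annotations should be given their primary step.
* The balanced all-steps score, with a = 1000/#pairs(S1,S2) and
  N″ = 1000 × #step-pairs, is algebraically the unweighted mean over step
  pairs of the pairwise scores — the 1000 factors cancel. The
  implementation computes it with the literal factors and the test suite
  verifies the identity to 1e-12 against a brute-force path-enumeration
  oracle (which delegates enumeration to networkx, keeping the two routes
  independent).

## Prey profiling and co-occurrence (prey, cooccurrence)

A prey's life-cycle profile is the fraction of its interacting baits per
step, all interaction types included; baits without a step annotation
accumulate in an "unknown" bin. Profiles are clustered by average-linkage
agglomerative clustering on Euclidean distance with cluster labels from the
mean-profile argmax; the prey-prey map is the Pearson correlation of binary
prey × bait incidence vectors (constant rows are masked as undefined, and
display order comes from clustering on 1 − r). Incidence is binary rather
than intensity-weighted by default.

The Jaccard index uses the standard union denominator and exact window
identity (site sets produced from a fixed genomic partition make identity
matching well-defined); both one-sided rank-sum comparisons against random
non-interacting RBP pairs and matrix clustering on 1 − J are provided.

## Synthetic-data generator (simulate)

The generator is the package's ground-truth instrument. Defaults define the
simulated study and were fixed from the experimental design, not fitted:

| parameter | default | meaning |
|---|---|---|
| n_baits / n_preys | 12 / 300 | 11 life-cycle baits (8 steps, cycled) + 1 replication-machinery negative control |
| type_proportions | 0.20 / 0.26 / 0.47 / 0.07 | direct / mediated / shielded / undetermined edge-type law |
| edges_per_bait | 15 | mean planted degree |
| background_mu, background_sigma | 13, 2 (log2) | log-normal protein baseline |
| noise_sd | 0.3 (log2) | replicate reporter noise, a typical TMT CV |
| effect_size / bait_effect | 3.0 / 5.0 (log2) | prey / bait-self enrichment in IPs |
| dropout_threshold | 512 | MNAR censoring: intensities below it go missing |
| n_fractions | 57 (fractions 10–66) | SEC design |
| sec_noise_sd | 0.15 (log2) | multiplicative SEC replicate noise |
| site_universe / site_base_rate | 2000 / 0.05 | binding-window universe and inclusion rate |
| overlap_rho | 0.50 / 0.20 / 0.30 / 0.55 | per-type site-sharing probability (ordering mirrors observed type medians: undetermined ≳ direct > shielded > mediated) |

Structure planted on top of the background:

* **Edge types per bait.** Types are drawn i.i.d. from type_proportions;
  undetermined-type edges attach only to dedicated baits whose IP is forced
  to fail QC in one RNase condition (no self-enrichment there), because
  "undetermined" is operationally a property of the bait's QC outcome, not
  an enrichment pattern. Other baits carry only determinable types.
* **Connectors.** One primary bridge prey is wired by direct edges to
  baits spanning ≥ 3 life-cycle steps, plus two smaller secondary
  connectors — interactome hubs come in groups, and a lone hub would make
  hub-level statistics untestable. Connector baselines sit 2.5 log2 units
  below the background mean: connectors are modeled as substoichiometric
  partners, giving them low prey/bait ratios while leaving detectability
  unchanged (batch-corrected z-scores are baseline-free).
* **Bait expressability.** Bait baselines are truncated to the expressed
  range (≥ μ − σ): baits in such studies are chosen for detectable
  expression and validated antibodies, and a bait below its own detection
  limit would fail QC for reasons unrelated to the planted design.
* **Negative control.** The control bait carries a private five-member
  complex, disconnected from the rest of the network; its members share the
  bait's baseline and co-purify at the bait's own enrichment, making them
  1:1-stoichiometry references.
* **SEC.** Complex members share a Gaussian apex at the fraction implied by
  the summed complex mass through a log-linear calibration (5000 kDa at
  fraction 10 down to 10 kDa at fraction 66); every protein also elutes as
  a monomer peak with per-protein width drawn from U(1.0, 2.5) fractions.
  Masses outside the calibration range clamp with a warning.
* **Binding sites.** Each protein includes each window independently at the
  base rate; for each true edge, private sites are copied symmetrically
  between partners with probability overlap_rho[type]. rho = 1 components
  are unified exactly (identical repertoires). Under rho = 0 the expected
  Jaccard is the independence baseline q/(2 − q).

**What the generator does not emulate** — and what passing tests therefore
do not demonstrate about real data: peptide/spectrum-level effects and
protein inference, isotopic impurity leakage between channels, retention
time structure, correlated (batch-structured) noise, interactions between
non-planted proteins, compositional distortion from highly abundant
contaminants, and co-fractionation of unrelated complexes of similar mass.
Recovery rates on synthetic data are upper bounds for real studies.

## Problem sizes in routine runs

The default synthetic study (12 baits × 11 channels × 312 proteins, 57 SEC
fractions, 500-1000 decoys and resamples) keeps a full pipeline run in
seconds and the complete test suite plus acceptance script in a few
minutes; all sizes are configurable upward for production-scale inputs.

## Known limitations

* The batch-correction attenuation of widely shared enrichment means a
  direct interactor's effective margin over the z threshold is smaller than
  for condition-specific interactors; with triplicates this occasionally
  drops one condition of a genuinely direct pair, misclassifying it as
  mediated or shielded. This is a property of the method, visible in the
  per-class recovery rates.
* The co-elution caller scores pairs only; it does not deconvolve
  higher-order complexes or estimate complex masses.
* Empirical decoy p-values are granular at 1/(n_decoys + 1); q-values
  inherit that granularity.
* The resampling p-value is conservative under heavy ties in F (small
  networks or tiny references).
* Conflicting RNA-dependency classes for a pair reported by two baits are
  resolved by a fixed precedence and flagged; no probabilistic reconciliation
  is attempted.
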