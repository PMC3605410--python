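# Methods

## Model and procedure

`coexdisrupt` compares the coexpression structure of two sample groups
(called High and Low throughout, after selected-line designs) over a shared
transcript set. The analysis chain is:

filter/normalize → per-condition unsigned adjacency → consensus network →
module detection → per-node network statistics → per-module preservation
correlations → sample-bootstrap empirical null → disruption Z-scores;
in parallel, moderated-t differential expression and, when genotypes are
supplied, AMOVA/MDS, founder-origin inference and allelic-imbalance scans.

Key modelling commitments:

- **Unsigned networks.** `a_ij = |Pearson cor|^β`: strongly anti-correlated
  transcripts count as coexpressed. β is a fixed configuration value
  (default 10), not auto-selected; `scale_free_fit` reports the signed
  log–log R² of the connectivity histogram purely as a diagnostic.
- **Preservation as correlation of node-statistic vectors.** For each
  module, the member vectors of kIM, kME, kMEall, clusterCoeff and MAR from
  the two networks are Pearson-correlated (`cor.kIM` etc.); `cor.ADJ`
  correlates the within-module upper-triangle adjacency entries. kMEall is
  aggregated per module by correlating the members' concatenated
  all-module kME vectors — one defensible reading of a "total eigengene
  connectivity" vector statistic; it is a convention, and is documented as
  such here.
- **The empirical null is the method's core.** Each bootstrap iteration
  pools all samples from both conditions, draws two pseudo-condition sets
  of the original sizes *with replacement*, builds both networks and
  records one preservation value per module/statistic plus per-transcript
  kIM differences. One iteration ⇒ one independent null draw (no all-pairs
  comparisons among the bootstrap networks, which would correlate draws).
  A `permute` mode (split a label permutation, without replacement) is
  available as an alternative null. Z = (obs − mean)/sd over the draws;
  disruption is declared on `cor.kIM` Z < −2 (all six statistics are always
  reported so other criteria can be applied), transcript-level flags use
  two-sided |Z| > 2 on the kIM difference.
- **Eigengenes** (first principal component of standardized member
  profiles, sign-oriented to correlate positively with members on average)
  are recomputed inside every network — observed or pseudo — from that
  network's own samples, with module membership fixed at the consensus
  partition.

## Tunable parameters

| parameter | default | meaning / why |
|---|---|---|
| `beta` | 10 | soft-threshold exponent; fixed, scale-free fit is diagnostic |
| `min_module_size` | 30 | smallest reportable module |
| `merge_cut` | 0.25 | merge modules with eigengene correlation ≥ 0.75 (conventional) |
| `n_boot` | 200 | null draws; 100 suffices for stable mean/sd at desk scale |
| `z_threshold` | 2 | disruption rule; strict inequality at the boundary |
| `detect_alpha`, `min_detect_fraction` | 0.01, 0.25 | probe detected if p < 0.01 in ≥ ⌈0.25·n⌉ samples (ceiling: conservative reading of "at least a quarter") |
| `cv_keep_fraction` | 0.5 | keep top half by CV = sd/mean, computed on the matrix scale as provided (no un-logging) |
| `de_fdr`, `imbalance_fdr` | 0.1 | BH thresholds for the expression and imbalance scans |
| `error_rate`, `switch_prob` | 0.01, 0.05 | HMM emission mismatch probability and per-marker recombination probability |

Filtering order: detection filter → CV filter → cross-dataset intersection
→ quantile normalization (per dataset, High and Low together so that
normalization cannot create artificial condition differences). The
detection and intersection stages are idempotent; a top-fraction CV cut is
inherently not (re-applying a top-50% rule halves the set again), which is
why the CV stage is parameterised by a fraction rather than pretending to a
fixed threshold. Quantile normalization maps each column onto the mean
order statistics; within-column ties receive the mean of the reference
values they span (ranks, and hence downstream correlations, are otherwise
preserved exactly).

## The synthetic generators

**Expression.** Each module m has a latent per-sample factor f_m; member i
is `l_i·f_m + √(1−l_i²)·ε + baseline_i`, with per-member loadings drawn
once from `loading ± hub_spread` (default 0.7 ± 0.25, mean-preserving,
shared by both conditions). The loading spread matters: it gives every
module a persistent hub hierarchy, which is exactly the structure the
preservation statistics measure — with identical loadings all members are
exchangeable, kIM vectors carry no signal, and preservation correlations
collapse to noise even for intact modules. Mean within-module correlation
remains `loading²`. Disruption rewires a chosen fraction of a module's
members onto an independent factor in the Low condition *with freshly
drawn loadings*: both the partner structure and the hub ranking change,
while every marginal mean and variance is untouched — connectivity change
without differential expression, the phenomenon the method targets.
Baseline log-intensities (N(7,1)) are shared between conditions.

What the generator does **not** emulate: array batch effects, correlated
noise between transcripts outside modules, heavy-tailed intensity
distributions, and overlapping/nested module structure. Passing tests
therefore demonstrate correctness of the statistics and calibration of the
null under a clean factor model, not robustness to microarray artefacts.

**Genotypes.** A homozygous founder panel (dosages 0/2, every marker
polymorphic) and per-sample chromosome copies simulated as first-order
Markov mosaics: switch probability `recomb_prob` per marker step, new
founder drawn from the current interval's target distribution excluding
the current founder (block lengths are then geometric with mean
`1/recomb_prob`). At "shifted" intervals the target distribution mixes the
uniform with a point mass on a group-favoured founder
(`shift_strength`); the founder state is re-drawn at any boundary where
the target distribution changes, so selected blocks do not bleed into
flanking intervals and non-shifted intervals stay distributionally
identical between groups. Diploid samples draw two independent copies
(unphased dosing); `ploidy=1` gives single mosaics whose interval-level
origin truth is unambiguous, used by the HMM-accuracy checks. Interval
truth is the majority founder across the interval's markers per copy.

## Numerical conventions and edge cases

- Adjacency diagonal is 0 and excluded from every connectivity sum, so kIM
  counts distinct partners only; constant transcripts get zero weight to
  all others (logged).
- clusterCoeff_i = (A³)_ii / (k_i² − Σ_j a_ij²) and MAR_i = Σa²/Σa are both
  defined as 0 when the denominator vanishes (isolated node), with a
  logged count.
- Modules with < 3 members have undefined preservation (NaN) and are
  excluded from Z-scoring; a null cell with σ = 0 yields NaN and an entry
  in `DisruptionResult.degenerate` — never a silent 0.
- Module detection clusters `1 − adjacency` directly (average linkage); a
  topological-overlap transform is available behind `use_tom=True` for
  users expecting the classic variant. The dendrogram is cut on a height
  grid at the height yielding the most clusters of size ≥
  `min_module_size` (ties broken toward the highest such height). The
  simpler rule "highest height with ≥ 2 big clusters" was tried first and
  systematically under-splits planted partitions — at that height two true
  modules are often already merged — so the most-clusters rule is used;
  it is deterministic and order-invariant.
- Bootstrap iterations that produce a constant transcript in either
  pseudo-matrix are redrawn (at most 10 attempts, then an error).
- The moderated t prior (d₀, s₀²) is moment-matched on log pooled
  variances; trigamma is inverted by log-domain bisection. Non-positive
  excess variance ⇒ d₀ = ∞ (all variances shrunk to s₀², normal reference);
  very large excess ⇒ d₀ → 0 (ordinary t). Degrees of freedom d₀ + d.
- Fisher tests: exact (scipy) for 2×2; wider group×founder tables use a
  Monte-Carlo test with fixed margins and the table-probability ordering
  (≥ 10⁴ draws, seeded). Empty founder columns are dropped first.
- Classical MDS truncates negative eigenvalues with a warning — expected
  for Manhattan distances, which are not generally Euclidean.
- AMOVA uses the squared-distance partition (SS_among/(k−1)) /
  (SS_within/(N−k)) with a permutation p-value; with zero within-group
  distance F is ∞ and only permutations reproducing the grouping tie it.
- Every stochastic stage takes an explicit seed; the pipeline derives
  per-stage sub-seeds from the master seed via `SeedSequence`, so full runs
  are byte-reproducible.

## Design choices that were genuinely open

- **Founder HMM scale.** No genetic map is modelled; transitions are
  uniform over non-self founders with a constant per-marker switch
  probability. Posteriors are averaged over each interval's markers and
  the argmax founder is taken per sample/interval (haploid reading of
  "most probable allele"); a diploid founder-pair emission mode is
  available behind `diploid=True` and marginalises pair posteriors to
  founders.
- **Two-sided transcript flags.** Connectivity can be gained or lost;
  transcript-level significance uses |Z| > 2 even though disruption at the
  module level is one-sided (Z < −2), since preservation below chance is
  what "disruption" means while an individual transcript's kIM can move in
  either direction.
- **Connectivity ranks** in the per-transcript output: rank 1 = highest
  kIM within its module in that network, so hubs have small ranks.

## Known limitations

- The desk-scale problem sizes used by the tests and the acceptance script
  (120 transcripts, 40 samples/condition, 100 null draws, 20 seeds) were
  chosen to make the full battery run in minutes; all statistics scale to
  thousands of transcripts but the O(n²·s) correlation and O(n³) triangle
  steps dominate for large n.
- Z-scores against the mixed-sample null **saturate and are not strictly
  monotone** in disruption strength: the null's σ grows when the pooled
  samples are most heterogeneous (near half-rewired), which compresses Z
  around intermediate disruption fractions even though the observed
  preservation itself decreases strictly. Median planted-module Z across
  seeds can therefore invert between adjacent disruption fractions (e.g.
  0.25 vs 0.5) while remaining far below −2 in both. Rankings of modules
  *within* one dataset are unaffected.
- The bootstrap null shares samples between the two pseudo-conditions of
  an iteration (and across iterations), which slightly raises the null
  mean preservation relative to disjoint splits; the `permute` mode
  provides the disjoint alternative and both are calibrated at desk scale.
- No probe-level microarray modelling, no covariate-adjusted DE designs,
  no QTL mapping or phasing; gene sets for enrichment are user-supplied.
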