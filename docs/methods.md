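# Methods

This note documents the models and procedures implemented in `androdyn`,
the design choices made where the workflow was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Preprocessing

The raw input is a per-protein table of treated and vehicle intensities (or
precomputed ratios) over 5 time points × 3 replicates. Proteins must have at
least `min_unique_peptides` unique peptides (default 2) and, by default, a
value in every cell ("identified in all replicates"); partial rows are never
imputed. Ratios are treated/vehicle at each matched (time, replicate); time
0 divides the two aliquots of the shared untreated baseline.

The standardization chain is, in order: (1) divide each sample column by its
median; (2) arithmetic mean over the three replicate ratios per (protein,
time); (3) log2; (4) per-protein z-score across the D = 5 time points using
the sample (n−1) standard deviation. Averaging is arithmetic on the
median-centered ratio scale because it precedes the log transform; a
geometric alternative is available (`average="geometric"`). Zero-variance
profiles cannot be z-scored and are removed with a log entry.

**A property of median centering worth knowing.** Dividing by the column
median estimates a per-sample scale factor under the assumption that most
proteins are unchanged in that sample. When a majority of proteins respond
coherently, the estimated "factor" absorbs part of the biological signal: a
population consisting entirely of one temporal shape collapses to constant
profiles. Centering is therefore a config flag (`median_center`, default
on). The test suite verifies factor removal on a mostly-null population and
verifies profile-construction exactness with centering off; clustering
itself is insensitive to the residual common-mode shift (archetype recovery
ARI ≈ 1.0 with centering on, at the default mixed population).

Replicate quality is summarized by a PCA of the per-sample log2 vectors and
the mean silhouette of replicates grouped by (condition, time) on the first
two components.

## Fuzzy c-means

Standard Bezdek alternating optimization of
J = Σ u_ic^m ‖x_i − v_c‖² with Euclidean distance: centroids are
membership-weighted means, memberships are inverse-distance ratios with
exponent 2/(m−1), and a point coincident with a centroid receives full
membership there. J is asserted non-increasing at every iteration.
Convergence is max |ΔU| < 1e−6 (Mfuzz-compatible magnitude), max 300
iterations, 5 restarts from symmetric Dirichlet(1) memberships with the
best objective kept; everything is deterministic given the seed.

The fuzzifier is estimated from the data dimensions with the
minimum-fuzzifier rule

m = 1 + (1418/N + 22.05)·D^(−2) + (12.33/N + 0.243)·D^(−0.0406 ln N − 0.1134),

which evaluates to 2.0126 → 2.01 at N = 4532, D = 5. Both correction terms
vanish for large D, so m decreases monotonically toward 1 (the hard k-means
limit). N here is the pre-membership-filter profile count.

**Cluster-count selection.** The elbow of J(k) is operationalized on the
log scale: the curve is anchored at the k = 1 baseline (total scatter
around the global centroid) and the selected k maximizes
log J(k−1) − 2·log J(k) + log J(k+1), i.e. the point of greatest relative
flattening. Two details matter. First, J(k) decays close to geometrically
before the true cluster count, so a second difference of raw J is maximal
at the smallest interior k for essentially any data — the log scale removes
that bias. Second, the k = 1 anchor makes the smallest requested k
selectable, which a purely interior rule cannot do (a two-cluster dataset
scanned over k = 2..10 must be able to return 2). A monotone-flat curve
(no positive second difference) returns the smallest k with a warning. The
full J(k) table is exported so the knee can be inspected by eye.

**Membership filter and archetype labels.** Hard assignment is argmax
membership (ties to the lowest cluster index, logged), retaining proteins
with maximum membership strictly greater than 0.4; the rest are reported as
fuzzy/uncertain. For k = 5 the clusters are named from their centroids: the
centroid with the largest positive bimodality score
min(max of first two time points, max of last two) − (middle value)
becomes C (signal mediators, elevated at both ends); the remaining four are
ordered by softmax-weighted time center of mass Σ t_j·softmax(v)_j and
named A, B, D, E from early to late. Any other k falls back to generic
`cluster_i` names with a warning.

## Enrichment, concept map, markers

Compartment/type enrichment is the upper tail of
Hypergeometric(M, K, n) at x observed in-cluster members of the category;
the universe is the retained (labeled) set with a known annotation of that
kind — `other/unknown` is excluded from both universe and categories, and
the universe choice is configurable. Defaults follow the printed workflow:
α = 0.001 for compartments, 0.05 for molecular types, one-sided, raw
p-values (no multiple-testing correction), with a Benjamini–Hochberg column
emitted for transparency.

Cluster–concept association uses the one-sided Fisher exact test on the
2×2 table over the labeled universe, retained at p < 0.001 and odds ratio
> 2. The sample OR ad/bc is reported as-is (infinite with a zero cell); a
Haldane–Anscombe 0.5-corrected OR is added and flagged whenever a zero cell
occurs, and the corrected value decides retention in that case.

Marker calling: each expression cohort is normalized per array (log,
median-centered, unit sd), tested gene-wise with an equal-variance
two-sample t-test (Welch optional) at α = 0.05, and a gene is a consensus
marker when significant with the same direction in ≥ 2 independent
datasets; genes significant in both directions are reported separately as
conflicts. The matched tumor/normal cohort uses a paired t-test at α = 0.01
by default — statistically proper for a paired design — with an
`unpaired` mode reproducing the plain two-sample analysis some studies
print for the same data.

## PPI integration

BioGRID TAB 3.0 (and, best-effort, MITAB) exports are filtered to physical
evidence (default: direct interaction / physical association semantics) and
human interactors, deduplicated and stripped of self-loops; identifiers are
uppercase gene symbols throughout, the join key for every table in the
package.

Cluster-pair over-representation is a hypergeometric over the edge
universe: among all M unordered pairs of labeled network nodes, K are
observed edges; for a cluster pair spanning n node pairs with x edges, the
p-value is P[X ≥ x]. The published workflow states only "p < 0.05" for this
step, so the test is a design choice here; a degree-preserving
rewiring-permutation p-value is available as a robustness column. Because
~15 pairs are tested simultaneously, the *flagged* set applies BH across
the family at α — without that, a global-null network would flag some pair
in half of all runs. Edge-share percentages are reported under both
conventions (over all counted edges, and over inter-cluster edges only).

The molecular-type interaction map connects two types when the fraction
cross-type edges / (|type1|·|type2|) strictly exceeds the threshold
(default 1%, with a 5% `figure4` preset); direction runs from the type
whose members sit earlier along the A→E flow (lower mean cluster rank) to
the later one, so reversing the ranks reverses every edge.

Cascades are all ordered triples (c, d, e) with cluster labels C, D, E,
PPI edges {c, d} and {d, e}, and c ≠ e; by default the terminal protein
must be a transcription regulator (the published cascade table's pattern),
switchable off. Both the triple count and the count of distinct (D, E)
groups are reported, since a tabulated cascade list can be counted either
way. The layout places members on a fixed 3×3 grid — columns C, D, E; rows
plasma membrane, cytoplasm, nucleus — with extracellular proteins mapped to
the membrane row and unknowns to the cytoplasm (configurable, logged).

## Synthetic data

The generator emulates the study's structure, not mass-spectrometry
physics (no isotopic impurity, reporter-ion compression, or
intensity-dependent noise). Defaults are the study conditions used
throughout the tests and the acceptance script:

- **Profiles**: n = 4500 proteins (tests use 2000 for speed; the methods
  scale trivially), five archetypes at 16% each plus 20% white noise,
  emulating the ~3/4 retained fraction after the membership filter. Each
  archetype is a fixed piecewise-linear template in standardized space —
  A peaks at 5 min and declines, B is elevated 5–30 min, C is bimodal,
  D rises from 30 min, E rises monotonically to a 60-min maximum. The
  template constants were chosen once for mutual separation (pairwise
  correlation ≤ 0.4 after z-scoring) within those qualitative shapes;
  planted classes that are collinear would be unidentifiable by any
  method. Profile noise is i.i.d. Gaussian, default sd 0.3 in standardized
  units; the log2 amplitude is 0.3 (ratio swings of roughly 0.7–1.4×,
  matching the modest changes expected within one hour). Per-replicate
  scatter (sd 0.08, mean-centered so replicate averages are exact),
  per-sample lognormal scale factors (sd 0.1, the target of median
  centering) and lognormal intensity baselines are layered on; treated =
  vehicle × ratio, so intensity noise cancels in the ratio. 3% of proteins
  get one unique peptide and 2% a missing cell to exercise the filters.
- **Annotations**: compartments from the annotated-proteome baseline
  (3.6% extracellular, 10.2% membrane, 56.6% cytoplasm, 29.5% nucleus,
  renormalized with a small unknown mass) and a 14-class type multinomial;
  planted odds multipliers (default 8) push A toward membrane/transporter/
  transmembrane-receptor, C and D toward nucleus, E toward
  nucleus/transcription/translation regulator. `bias_odds=1` is the null.
- **PPI**: Erdős–Rényi at base rate 0.002 (≈17k edges at n = 4500, the
  scale of the real network), multiplied by pair-excess factors (default
  5× for C/E, D/E, C/D) and optional exact-degree hubs.
- **Concepts**: membership probability 0.04, multiplied by `overlap_odds`
  (default 10) for the designated cluster, round-robin over A–E.
- **Markers**: six cohorts of 20 vs 20 Gaussian samples; planted genes
  (default 100) shifted ±2 sd in a random ≥2-subset of cohorts; the paired
  cohort has 52 tumor/normal pairs with ±1.5 sd shifts.

Every generator is a pure function of (parameters, seed). Passing tests on
these data show the machinery is correct and calibrated (null settings
produce false-positive rates compatible with the nominal alphas; planted
effects are recovered); they do not certify performance on real TMT data,
whose noise is non-Gaussian, intensity-dependent and ratio-compressed.

## Numerical choices and limitations

- z-scores use ddof = 1; "more than two unique peptides" is read as ≥ 2
  (configurable), matching the quantification summary rather than a strict
  reading.
- FCM restarts default to 5; the elbow scan and pipeline use the seed in
  the run config, and the run manifest records seed and config hash.
- Argmax ties and hub-degree ties break deterministically (lowest index /
  lexicographic).
- Test problem sizes (n = 2000 profiles, 20-seed calibrations, ≤100-node
  brute-force oracles) were chosen so the whole suite exercises every claim
  at comfortable statistical margins while staying quick on a laptop.
- The package does not parse raw spectra or search-engine output, does not
  impute, and does not attempt to reproduce dataset-dependent counts from
  any particular proteome/BioGRID/GEO snapshot; those depend on inputs the
  user supplies.
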