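# Methods

This note documents the statistical model, the conventions that were fixed
where several were defensible, the synthetic-data model and its limits, and
the numerical choices. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Metabolic phenotyping

Insulin resistance is scored as HOMA-IR = glucose [mg/dL] × insulin [mU/L]
/ 405, or glucose [mmol/L] × insulin / 22.5 when the mmol/L flag is set
(405/22.5 = 18, the mg/dL-per-mmol/L conversion for glucose; the two modes
agree exactly under that conversion, which is property-tested). Units are
never auto-detected. The MUO/MHO cut-off is HOMA-IR ≥ 3, boundary
inclusive, with no tolerance band.

When a cohort file supplies both a HOMA column and glucose/insulin, the
stratifier recomputes HOMA and counts records where the two disagree by
more than 0.01. The recomputed value drives stratification unless
`use_precomputed` is set. This is deliberate: published descriptive tables
are not always arithmetically consistent with the printed formula, and the
pipeline should surface such inconsistencies, not hide them.

## Network model

Within a stratum the 13 node variables are modelled as a Gaussian graphical
model. With R the Pearson correlation matrix (the binary HTN flag enters as
0/1, i.e. point-biserially; no polychoric machinery) and P = R⁻¹, the
partial correlation is Rp_ij = −P_ij/√(P_ii·P_jj) — equal to the
correlation of the residuals from regressing i and j on the remaining 11
variables, which is the oracle the tests compare against at 1e−8.

Estimation requires n ≥ p + 2 and a correlation matrix with smallest
eigenvalue above 1e−10; otherwise an estimation error is raised that points
to the optional ridge term (λ added to the diagonal, then re-standardised;
default λ = 0). The ridge exists because a stratum of n ≈ 56 with 13
variables can be ill-conditioned on resamples.

**Edge selection.** Each pair is tested with t = Rp·√(df/(1−Rp²)),
df = n − 2 − g with g = 11 conditioned variables (the standard
partial-correlation t-test). The default rule keeps pairs with two-sided
p < 0.25 — a deliberately liberal screen whose rationale is to avoid
prematurely discarding weak but structurally relevant edges. Because the
phrase "Rp values of p < 0.25" can also be read as a magnitude rule, a
`magnitude` mode (|Rp| > threshold) is provided; the p-value reading is the
default. No multiple-testing correction is applied across the 78 tests —
the screen is intentionally a per-pair level-0.25 test, and the null
calibration experiment verifies exactly that property. HOMA-IR is retained
as a node even though it also defines the strata; the resulting range
restriction within each stratum is a property of the design being
reproduced, not an artifact to correct.

## Graph statistics and conventions

All distance-based statistics use **unweighted** hop-count distances on the
binary adjacency. This convention is forced by the report format being
mirrored: on a connected 13-node graph every closeness value is then 12/k
for an integer k (a property the suite asserts), which only holds for
integer distances. The signed Rp weights are retained for edge sign,
file export and community detection.

* Closeness: (reachable count)/(sum of distances to reachable nodes);
  0 for an isolated node.
* Harmonic closeness: mean over the other n−1 nodes of 1/d, with 1/∞ = 0,
  hence well-defined on disconnected graphs.
* Betweenness: Brandes accumulation, unnormalised raw pair counts with
  fractional credit across equally short paths, endpoints excluded. The
  "bridge node" of a stratum is the node ranked first on betweenness.
* Eigenvector centrality: leading eigenvector of the binary adjacency,
  scaled so the top node scores exactly 1. The power iteration runs on
  A + I (same eigenvectors; the shift makes the Perron root strictly
  dominant so bipartite graphs cannot oscillate), tolerance 1e−10, at most
  1000 iterations, with an iteration-count error on non-convergence.
* HITS: on an undirected graph authority = hub = the leading eigenvector
  direction; reported with unit L2 norm (so the two columns agree to
  numerical tolerance rather than construction order).
* Triangles/clustering: edges among neighbours; coefficient
  triangles/(deg·(deg−1)/2), 0 below degree 2.
* Global metrics: density m/(n(n−1)/2) exactly; diameter = largest finite
  eccentricity; average path length = mean of finite pairwise distances;
  average clustering = mean of node coefficients. Edgeless graphs raise an
  undefined-metric error rather than returning sentinels.
* Ranking: descending, ties broken by schema order (stable sort).

**Louvain.** Modularity uses Q = (1/2m)Σ[A_ij − k_i k_j/2m]δ(c_i,c_j) with
A = |Rp| by default (`absolute` mode) or unit weights (`binary`). The
heuristic is the standard two-phase greedy optimisation at resolution 1.0;
node visiting order is a seeded permutation, so results are deterministic
given (seed, node order), and the seed is recorded in every output. Labels
are contiguous integers in order of first appearance along the schema
order. The suite checks Louvain's Q against exhaustive enumeration of all
partitions on small graphs (never exceeds the optimum; attains it on a
two-clique fixture).

## Synthetic cohort model

Per stratum, a target partial-correlation matrix Rp is converted to a
correlation matrix by building the unit-diagonal precision P (off-diagonal
−Rp_ij), inverting, and re-standardising; positive definiteness is checked
at parameter construction and the estimation map provably inverts this
construction (round-trip tested at 1e−8). Latent draws are rescaled to the
published per-stratum means/SDs; BMI is floored at 25 (study eligibility),
concentrations at small positive values, questionnaire scores at 0 — with
the default moments these truncations move means by well under the
3·SD/√n testing tolerance. HTN is produced by thresholding its latent
coordinate at the quantile matching the target prevalence (14.4% MHO,
51.8% MUO by default), which keeps its correlations coherent with the
latent model rather than bolting on label noise.

**The HOMA-IR hard guarantee.** The emulated descriptive table is
internally inconsistent: its MUO glucose and insulin means imply
glucose×insulin/405 ≈ 1.4, below the cut-off of 3, while its printed
HOMA-IR means exceed 10. The generator resolves this normatively rather
than reproducing the contradiction blindly:

* the HOMA *node* column is drawn from the latent model at the printed
  HOMA moments (so the 13-column network honours the target Rp and the
  published marginals);
* stratum membership is driven by *recomputed* HOMA, and any record whose
  glucose×insulin lands on the wrong side of 3 has its insulin minimally
  re-targeted (insulin ← h·405/glucose with h drawn just beyond the
  cut-off, 3 ± [0.05, 0.5]). With the default moments this touches almost
  no MHO records but nearly every MUO record.

Consequences, documented rather than hidden: MUO insulin sample moments do
not match the printed insulin mean/SD (the moment property test therefore
excludes insulin); in the MUO stratum insulin becomes strongly negatively
coupled to glucose, so recovery experiments place designated true edges on
insulin-free pairs and absorb the known glucose–insulin artifact in the
false-positive budget. The default stratum sizes (132/56) are exact by
construction, not in expectation.

What the generator does **not** emulate: non-Gaussian marginals (skewed
questionnaire distributions), measurement error, missing data, exclusion
screening, or any dependence between demographics and the node variables.
Passing tests therefore demonstrate correctness of the estimation and
metric machinery under a coherent latent-Gaussian cohort, not robustness
to the messiness of real field data.

**Scenarios.** Named true networks ship as defaults: `mho_like`
(depression–anxiety–stress triangle, stress linked to NP2/NP3/BMI),
`muo_like` (NP3 hub wired to lipids/glycemia plus a CholesT–TAG edge),
`null` (empty, for calibration) and `recovery` (six |Rp| = 0.4 edges with
a clean support for recovery experiments). Magnitudes (0.3–0.45) are
module defaults chosen to be moderate yet comfortably positive definite.

**Experiments.** `selection_calibration_experiment` (default 500
replicates of a single null stratum, n = 150) measures the per-pair
selection frequency of the screen; `recovery_experiment` runs the full
generate → stratify → estimate → select pipeline per replicate and reports
sensitivity on the designated support (all entries 0 or |Rp| ≥ 0.3,
enforced) and the false-positive rate on null pairs, with Monte-Carlo
standard errors. Problem sizes in the acceptance script (500×n=150
calibration; 20×n=2000 recovery) are the package's standard experiment
sizes; both run in seconds.

## Determinism

One master seed; per-stratum and per-replicate streams are derived through
`SeedSequence` and logged in the ground-truth sidecar and run manifest.
Identical configuration and input produce byte-identical CSV artifacts
(floats are serialised via `repr` and re-parsed with correctly-rounded
`float()`, so read∘write is the numeric identity). Manifests differ across
runs only in timestamps.

## Known limitations

* Pearson/point-biserial treatment of the single binary node is a
  simplification; tetrachoric-style estimation is out of scope.
* No graphical lasso / EBIC model selection and no bootstrapped edge
  stability — the per-edge screen is the implemented (and calibrated)
  selection rule.
* Weighted-distance variants of closeness/betweenness/path metrics are
  deliberately out of scope, not merely unimplemented.
* Per-node centralities of any particular published table are not
  recomputable without that study's raw data; the package reproduces the
  *procedure* and its arithmetic identities (e.g. density = m/78), and
  validates the machinery against oracles and synthetic ground truth.
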