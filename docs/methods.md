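# Methods

## Design construction

A definitive screening design for k factors consists of 2k + 1 runs: the
rows of a conference matrix C of order k, their element-wise negations
(fold-over pairs), and one overall center run. A conference matrix has a
zero diagonal, ±1 off-diagonal entries and CᵀC = (k − 1)·I; this structure
is what makes every main-effect contrast exactly orthogonal (in integer
arithmetic) to every pure-quadratic and two-factor-interaction contrast,
so a single screening block supports second-order modeling. C is built by
the Paley construction (quadratic-residue character over GF(q)) whenever
k − 1 is an odd prime; orders 10 and 16, which have no prime-field Paley
construction, are stored as literal tables — order 10 from the Paley
construction over GF(9), order 16 from the doubling
`[[C, C+I], [C−I, −C]]` of the order-8 skew matrix — and re-verified
against the Gram identity by the test suite. Any valid DSD of a given
order is equivalent up to row/column permutation and sign switching; no
particular instance is privileged.

The reference medium lies outside the coded ±1 space, so reference rows
carry NA coded levels, are stamped on each donor block, and never enter
model features. Run order is randomized per block with a recorded seed;
run identity follows the formulation, not the position.

## Synthetic donor population

Each donor carries one full second-order surface per response
(intercept, k main effects, k pure quadratics, all two-way interactions,
coded units). The generator separates the *population* surface from
*donor deviations*:

- **Population.** Each coefficient class has a sparsity (fraction of null
  components) and active magnitudes drawn as floor + |N(0, scale)|, so a
  screen always contains detectable effects. Quadratics are negative
  (interior optima); quad-active components get an optimum coordinate
  drawn uniformly from ±`optimum_range`. One designated component is
  toxic at its high level (main effect −8 on viability), which splits the
  screening runs into <75 % and >75 % viability groups.
- **Donor deviations.** Effect sizes are donor-specific: each donor
  multiplies every active coefficient by 1 + t₃-distributed noise (scaled
  to the class SD), and shifts the optimum coordinate of quad-active
  components by a t₃ jitter. The heavy tails are deliberate: occasionally
  a donor responds idiosyncratically to a component, which is what makes
  mean-based pooled modeling fragile while median-based consensus stays
  stable. Null components stay null for every donor, so the sparse
  support is a population property. Intercepts and reference performance
  get additive Gaussian donor shifts.

Default scales (expansion): intercept 23 units (donor SD 0.75), two pure
main effects of magnitude ≥ 3, three interior-optimum components with
curvature ≈ −1.5 and optima within ±0.6 (donor jitter SD 0.45), one
interaction ≈ ±0.8, replicate noise SD 0.8 units, reference medium
30 ± 1. This puts the bulk of screening-run medians between the mid-teens
and low thirties with the reference near the top, and makes replicate-level
model RMSEs of ~1 unit attainable. Viability uses intercept 80 %
(donor SD 3), the toxic component, three moderate mains and one quadratic,
clamped to [0, 100]. Responses are simulated per run × replicate as
surface value + Gaussian noise, clipped to the response bounds.

The planted-optimum scenario replaces the population surface by a sparse
concave quadratic: curvature −q on the off-center components of a chosen
x*, main = 2q·x*, so the argmax is exactly x*. Donor deviations rescale
curvature only (a vertex is invariant under rescaling), so all donors
share the optimum — the configuration used to test end-to-end recovery.
Curvature on *all* twelve components is deliberately avoided: twelve
mutually correlated quadratic columns cannot be resolved from 25 runs,
and strength above ~1.5 would drive the expansion surface into its zero
floor at far design corners.

### What the simulator does not emulate

Mechanistic T-cell biology (activation kinetics, cytokine response,
time-courses), correlations between the two responses beyond shared
component activity, batch/plate effects, non-Gaussian measurement error,
and real component identities or units. Passing tests therefore show the
*pipeline* behaves correctly under its own statistical assumptions — not
that those assumptions hold for any particular wet-lab system.

## Competitive modeling

Features are the equation term sets in fixed order (mains, quadratics,
interactions lexicographic); columns are centered and scaled, zero-variance
columns dropped and recorded. Replicates enter as separate observations;
cross-validation folds are formed over *runs* (all replicates of a run
share a fold) and the scaler is re-fit inside every training fold, so no
information from held-out runs reaches the fit. CV metrics are pooled
held-out RMSE and R² (SST on held-out values).

- **Stepwise OLS** minimizes AIC = n·ln(RSS/n) + 2p bidirectionally from
  the intercept with the full term set as scope; adds are scored in one
  pass by projecting free columns onto the orthogonal complement of the
  current design (exact RSS per add without refitting), drops refit the
  reduced model; rank-deficient moves are rejected. With the penalty of 2
  per term, pure noise with five spurious predictors retains ~0.7 terms
  on average and returns the intercept-only model about half the time —
  the exhaustive-neighbor oracle in the tests confirms the returned model
  always beats every single add/drop.
- **Elastic net** tunes mixing l1_ratio ∈ {0, .25, .5, .75, 1} × 50
  log-spaced penalties (glmnet-style data-driven maximum, min-ratio 1e-4)
  by grouped CV; ties go to the larger penalty then larger mixing (the
  sparser model); the winner is refit on all data. The pure-L2 corner is
  solved in closed form via SVD; zero penalty falls back to OLS.
- **Random forest** tunes the feature-subsampling fraction
  ∈ {1/3, 1/2, 2/3, 1} at 500 trees (both overridable); predictions are
  bounded by the training response range by construction.

Ranking: ascending CV RMSE, descending CV R² on ties. Only elastic-net
and forest candidates are eligible for the finals; stepwise OLS competes
for reference but is excluded for its weaker robustness to overfitting at
screening sample sizes. Train metrics are stored alongside CV metrics;
selection is driven by CV. Model ids follow `b{block}.model{n}{e|v}`.

A structural note on sample size: at the run level a DSD has only 2k + 1
distinct points, so the mains+quadratics equation (2k terms) is already
saturated and the full second-order equation heavily so. Unregularized
fits of the richer equations therefore generalize poorly across held-out
runs, and the CV ranking frequently prefers the main-effects equation
with a regularized fit — the motivation for competitive selection rather
than committing to one equation.

## In-silico search and consensus clustering

Candidates are uniform over the continuous coded cube, not the three
design levels; constraints fix a component exactly or bound it (the
default fixes c02 at its mid level, the equality reading of restricting
an expensive component). One shared candidate set serves all models; each
final model contributes its top 40 (ties broken by row index), duplicates
retained.

The pool is centered and scaled; the Hopkins statistic
H = Σu/(Σu + Σw) (m = ⌈0.1 n⌉ uniform pseudo-points in the bounding box
vs. m sampled real points, nearest-neighbor distances, H ≈ 0.5 uniform,
→ 1 clustered) quantifies clustering tendency. The pseudo-points use a
spawned child of the supplied seed so they can never replay the stream
that generated the data. k-means (Lloyd, k-means++ seeding, best of 25
restarts) with the cluster count taken from config (default 6; the elbow
curve of total within-cluster SS is computed as a diagnostic rather than
an automatic rule). Silhouette widths use Euclidean distance with the
singleton-zero convention.

Each cluster collapses to its component-wise median formulation
(midpoint of central order statistics at even counts); composition is
tabulated by response and donor of origin. Back-evaluation predicts every
cluster medium in all final models and summarizes per response by median
and IQR across donors. Selection requires a cluster's expansion members
to represent every training donor, then ranks by predicted median
expansion; if fewer than the requested number of clusters qualify, the
remaining slots are filled from the ranked rest with an explicit warning
(keeping the confirmation design a fixed size), and if none qualify the
best-ranked cluster is returned flagged.

## Baselines and evaluation

The traditional arm pools all donors' expansion data (donor identity
discarded) into one stepwise-AIC OLS on the *main-effects* equation — the
analysis a sequential workflow would run after its single screening
round, curvature being the business of the (omitted) second experiment.
Its six test media are chosen greedily by predicted expansion subject to
a pairwise L∞ separation of 0.5 (relaxed with a warning if infeasible).
The naive ensemble is the component-wise median of the expansion-filtered
pool — clustering ablated.

The confirmation experiment simulates fresh test donors drawn from the
same population (selected cluster media + six baseline media + reference,
randomized complete blocks). Experimental summaries average replicates
within donor first, then take median and IQR across donors; each arm's
predictions are compared to the experimental medians by absolute error.
Both arms share the test-donor sampling noise (median of four fresh
donors); the individual-model arm is nearly unbiased at consensus media
(the cross-model median cancels per-model selection optimism), while the
pooled main-effects model over-extrapolates at its corner-selected media.
The margin between the arms is real but modest relative to four-donor
sampling noise, so individual replicates of the comparison can flip.

## Reproducibility and numerics

One master seed derives a named seed per stage via `SeedSequence`
(all below 2³¹); identical configs give byte-identical CSV/JSON outputs,
hashed into a run manifest. Degenerate inputs fail loudly: odd or
unsupported conference orders, conflicting constraints, zero-variance
responses, missing donor models, k above the point count. Elastic-net
paths run at tolerance 1e-6 (max 20 000 iterations); stepwise ties break
toward the current model at 1e-10; k-means monotonicity of the elbow is
asserted at 1e-9 under sufficient restarts.

Problem sizes in the test suite are scaled down from the package defaults
(candidate grids of 10⁴–2×10⁴ instead of 10⁵, forests of 100 trees with a
two-point tuning grid, 20-lambda paths, elastic-net-only modeling in the
replicated end-to-end studies); structural counts are invariant to these
sizes and the statistical checks were designed at the reduced sizes from
the start.

## Known limitations

- The quadratic coefficients of a DSD are weakly identified (three center
  observations per component, mutually correlated quadratic columns);
  optimum *locations* are recovered well only when curvature is sparse.
- Cluster-count selection is not automated; the elbow/silhouette output
  is diagnostic and the default of six follows the study design the
  package emulates.
- The pooled-vs-individual comparison depends on how the traditional arm
  is specified; richer pooled models narrow the gap (see the baselines
  section).
- Donor deviations are independent across components and responses; real
  donor covariance structure is not modeled.
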