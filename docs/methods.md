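# Methods

This note documents the models and numerical choices behind `convscan`, in
the spirit of the model documentation shipped with simulation and inference
packages: what is computed, under which assumptions, and where the design
was genuinely open.

## Trait reconstruction

Ancestral values of the continuous habitat trait (temperature in °C, or
depth as log10 meters — the log scale follows the adiabatic gas law and
keeps bin widths meaningful across three orders of magnitude) are estimated
under Brownian motion on the fixed, rooted species tree.  The estimator is
a two-pass Gaussian message scheme: the upward pass combines child messages
with precision weights 1/(v + t) (conditional variance plus branch length),
the downward pass folds in the rest of the tree, and each node's estimate
is the precision-weighted combination of both.  On a fixed tree this equals
the GLS/ML solution obtained from the full BM covariance matrix (the test
suite checks the identity to 1e-8 on random 10–30 tip trees), while running
in linear time.  Consequences of the model:

* estimates are convex combinations of tip values (never outside the
  observed range), invariant to rescaling all branch lengths, and
  equivariant under shifts of the trait;
* point estimates only — no uncertainty is carried into scenario
  construction.  This mirrors common practice but means spurious
  transitions near a cutoff are possible; the bootstrap calibration, not
  the reconstruction, is the guard against over-interpretation.
* zero-length branches are replaced by 1e-8 × tree height so precision
  weights stay finite; at that magnitude the estimates are unchanged to
  well below reporting precision.

Tips without trait values are pruned first (`prune_to_traits`, ≥ 4 shared
taxa required); alignments may still contain those taxa, since site scoring
prunes the tree per column anyway.

## Convergent scenarios

Node values are binned with a fixed width anchored at the minimum observed
node value: bin(v) = floor((v − min)/w).  Defaults are w = 1.75 °C for
temperature and w = 0.2 log10 m for depth.  A candidate cutoff sits at
every interior bin boundary min + k·w.  The anchor is a design choice — any
anchor produces the same partition family up to deduplication, and
min-anchoring is deterministic.

For a cutoff c, nodes with value ≥ c are convergent; if the root lands on
the convergent side the orientation is inverted (value < c convergent), so
the root is always ancestral and the direction of each transition is
well-defined.  A branch is identified with its child node; convergent
branches are those whose child is convergent, and transition branches are
the edges whose parent is ancestral and child convergent.  Reversions
(convergent parent, ancestral child) are not transitions, and a later
re-entry into the convergent state below a reversion counts as a new
independent transition.

Scenarios with identical convergent branch sets are deduplicated (first,
i.e. lowest, cutoff kept) and scenarios with fewer than `min_transitions`
(default 5) independent transitions are dropped.  The transition minimum is
the safeguard against phylogenetic pseudoreplication: a single colonisation
event shared by many descendant taxa should not masquerade as repeated
evolution.

## Substitution model

Each site evolves under one profile π from a K × 20 profile set (a
CAT-style site-heterogeneous mixture).  The per-profile process is the
profile-driven one-parameter chain q_ij = β π_j (i ≠ j), the natural
"CAT-Poisson" choice: it is reversible with stationary distribution π and
admits the closed form

    P_ij(t) = e^{−βt} δ_ij + (1 − e^{−βt}) π_j .

β = 1/(1 − Σ_k π_k²) normalises the process to one expected substitution
per site per unit branch length at stationarity, so branch lengths keep
their usual substitutions-per-site meaning regardless of the profile.
There is no across-site rate variation (single rate class) and no
exchangeability matrix modulation; both would be worthwhile extensions but
neither admits the exact closed-form tests used throughout the suite.
Profile rows are floored at 1e-6 and renormalised, keeping likelihoods
finite and the conditioned process well-defined.

Two profile sets are bundled.  Both are *synthetic* constructions of this
package (the file names say so): `c10` holds ten chemically-motivated
class-weighted profiles (hydrophobic-heavy, charged-heavy, aromatic, …,
uniform) and is the default for simulation studies; `c60` holds sixty
seeded Dirichlet draws around random residue subsets, matching the
cardinality commonly used for empirical CAT analyses.  Any profile TSV
(id + 20 frequencies in ACDEFGHIKLMNPQRSTVWY order) can be supplied
instead, which is the intended route for empirically estimated categories.

## Site scoring

For a column y and a scenario s, four likelihoods are defined by assigning
a process to every branch and running Felsenstein pruning (root prior: the
ancestral profile):

* **null** — one profile everywhere;
* **PC** — convergent branches use a second profile π_C, nothing forced;
* **OC** — one profile, but transition branches are conditioned on at least
  one substitution event;
* **PCOC** — convergent branches use π_C and transition branches are
  conditioned under π_C.

For the closed-form process, conditioning on at least one event makes the
child state an independent draw from the profile: P*_ij = π_j for all i.
This is the unique consistent "one change" contract for this chain, and the
same rule is used by the simulator, so scoring and simulation agree exactly.

The reported statistic is PP = expit(logL_PCOC − logL_null) with logL_null
maximised over the K single profiles and logL_PCOC over the K(K−1) ordered
pairs — an ML (not model-averaged) profile assignment under equal model
priors.  Each site's maximum PP across all viable scenarios is reported,
with the arg-max scenario and cutoff.  The pruning recursion is vectorised
across alignment columns, and columns are grouped by gap pattern so each
pruned tree is built once; because the closed form reduces each branch
message to an axpy plus a dot product, a 64-tip × 500-column × 90-pair scan
takes seconds.

Gap handling: taxa with '-' (or 'X', '?', '.') at a column are pruned from
the tree for that column, suppressing unary nodes and summing branch
lengths.  A scenario is re-projected onto the pruned tree (retained nodes
keep their state; transitions are recomputed) and skipped for the column if
it no longer carries `min_transitions` transitions.  Columns with fewer
than 4 ungapped taxa, or no viable scenario, are reported `skipped_gaps`.
In rare gap patterns the pruned root (the MRCA of ungapped taxa) can lie
inside a convergent clade; the root prior intentionally remains the
ancestral profile, and the transition filter governs whether such a
projection is still testable.

## Bootstrap calibration

Sites with max PP below 0.5 are reported `below_threshold` and not
bootstrapped (the same computational shortcut used in practice).  For each
remaining site, on its own gap-pruned tree and with its ML profile pair and
best scenario:

* the **null arm** simulates `n_sims` (default 1000; 200 in the scaled-down
  experiments) columns under the ancestral profile with noise — each
  simulation draws its profile from Dirichlet(c·π_A), default concentration
  c = 100, giving mean π_A and realistic per-frequency jitter of a few
  percent;
* the **convergent arm** simulates `n_sims` columns under the un-perturbed
  ML pair with transitions placed by the best scenario.

Both arms are rescored with the same scenario and profile set as the
observed column.  The upper threshold is the (1−α) empirical quantile
(inverse-ECDF, type-1: smallest order statistic with ECDF ≥ p) of null-arm
PPs; the lower threshold is the β quantile of convergent-arm PPs, with
α = β = 1 − confidence (default 95%).  A site is `adaptive` when its PP is
at or above the upper threshold and strictly above the lower one,
`non_adaptive` in the mirror case, and `unresolved` in the middle band or
wherever the two shaded regions overlap.

Known caveats, deliberate and documented rather than hidden:

* the observed PP is a maximum over scenarios while the simulations are
  scored under the single best scenario, so marginally flagged sites are
  slightly anti-conservative; under the default study conditions the
  overall null false-positive rate remains far below α (the suite measures
  it directly);
* a `diagnostic_equal_profiles` mode re-runs the null generator on both
  arms, verifying that thresholds then overlap and the unresolved band
  spans the observed PP;
* optional branch-length noise (lognormal multipliers, off by default)
  makes the calibration more conservative when the tree is uncertain.

Every site draws its RNG stream from (seed, site index), so calls are
bit-reproducible and independent of scan order.

## Structural-context statistics

The comparison group for all contrasts is every site *predicted
non-adaptive* — bootstrap `non_adaptive` calls together with
`below_threshold` sites — versus sites called `adaptive`; `unresolved` and
`skipped_gaps` sites are omitted, since their status reflects sampling
rather than biology.

* **B-factor (flexibility):** values are transformed by the rank-based
  inverse normal map r ↦ Φ⁻¹((r − 0.5)/n) (average ranks for ties; the
  offset convention is stated because implementations differ in the third
  decimal) and modelled as depth × temperature adaptiveness with a two-way
  Type III ANOVA under sum-to-zero contrasts (statsmodels OLS + anova_lm).
* **Secondary structure / exposure composition:** 2 × c count tables are
  tested with the exact conditional test — full enumeration of tables with
  the observed margins, summing the probability of every table no more
  probable than the observed one (two-sided, tolerance 1e-12 on the
  comparison).  This generalises Fisher's exact test to r × c; totals
  above 500 are directed to a seeded Monte Carlo variant.

## Synthetic data and what the tests show

The simulator is first-class: it draws root states from the ancestral
profile, evolves branches under the closed-form process, and applies the
one-change contract on transition branches — exactly the generative model
the scoring assumes.  The default study conditions for the discovery
experiment (64-tip balanced tree, branch length 0.3, a 7-transition
scenario covering 16 tips, 100 planted sites under a hydrophobic→charged
shift, 400 null sites, 200 bootstrap simulations per arm at 95% confidence)
were chosen once as a realistic desk-scale stand-in for a transcriptome
analysis and are frozen in the test suite and acceptance script.

Passing tests therefore demonstrate correctness of the machinery (pruning
equals exhaustive enumeration; the closed form equals the matrix
exponential; the two-pass BM estimator equals GLS; the bootstrap controls
its stated error rates *under the model*).  They do not demonstrate that
real enzyme alignments satisfy the model: real data bring profile
misspecification, rate variation, indels treated as missingness, and
correlated traits, none of which the generator emulates.  Performance
numbers from the planted experiment are upper bounds on what matched field
data would give.

## Limitations

* Brownian motion for the trait — no Ornstein–Uhlenbeck pull, no rate
  shifts, no reconstruction uncertainty.
* Profiles are taken as given, not estimated from the alignment.
* No indel model: gaps are missingness, so convergent insertions/deletions
  are invisible.
* No multiple-testing correction across sites; the per-site bootstrap
  controls per-site error rates only.
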