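# Methods

## Risk labels and binarisation

Patients are labelled by the 5-year rule on bone-metastasis-free time: an
event at `time <= 5` years is high-risk (1), survival with `time > 5` is
low-risk (0), and a patient censored at or before 5 years is *excluded* —
kept in every table with an explicit marker, never dropped silently, because
excluded patients still contribute to the survival analysis of predicted
groups. Input time units (years or months) are declared in the configuration
and converted to years before thresholding.

Expression is binarised per gene at its median: strictly above the median
maps to 1, at-or-below maps to 0, so a constant gene becomes an all-zero row
rather than an error. Medians are computed once over all retained
(non-excluded) patients of the analysis cohort, not per split; nothing in
the procedure is split-specific before model fitting, and computing medians
per split would let the binarisation of one patient depend on which split
they landed in.

## Conditional mutual information and the permutation test

For candidate ordered pair (modulator B, dependent A) the score is

    CMI(A|B) = I_high(A; risk) − I_low(A; risk)

where the strata are the first and last `floor(0.35 · n)` patients after
sorting by B's expression. Stratification uses B's *continuous* values: the
35% tails of a binary vector are degenerate (the tail boundary would fall
inside a tie block), and sorting continuous expression preserves the
intended extremes. Ties in B are broken by a seeded random shuffle applied
before a stable sort, which makes the strata deterministic yet unbiased.
Mutual information is the plug-in estimate on the empirical 2×2 table, in
bits (the base cancels in the permutation test), with 0·log 0 := 0.

Significance is a two-sided permutation test on |CMI|: B's expression
vector is permuted, the CMI recomputed, and

    p = (1 + #{|CMI_perm| >= |CMI_obs|}) / (n_perm + 1).

Two-sided because the score is a signed difference and either sign indicates
modulation; the +1 pseudocount avoids p = 0 and is the standard permutation
estimator. Permuting B and re-sorting assigns the two strata to uniformly
random disjoint patient subsets of size `floor(0.35 · n)`, so the null CMIs
are computed directly on vectorised random index sets — mathematically
identical to the literal permute-then-sort route (asserted by a unit test)
and orders of magnitude faster. Each pair's random stream is seeded by
(master seed, pair index), making results independent of evaluation order.

Edges with p < 0.05 (raw, following the reference procedure; no
multiple-testing correction) form the directed network, modulator →
dependent. Both orientations of every PPI edge are tested, and both may be
significant — the score is built from an interaction that is statistically
near-symmetric, so a strong dependency often appears as a 2-cycle.

Degree diagnostics fit log10(frequency) against log10(degree) by least
squares over non-empty positive-degree bins, reporting R² and the Pearson
correlation separately for in- and out-degree; with fewer than three
distinct degrees the fit is reported as NaN rather than a meaningless line.

## Structural controllability and driver sampling

The minimal number of external inputs that renders a directed network
structurally controllable is N − |maximum matching| in the bipartite split
(each gene contributes an out-copy and an in-copy; each arc u→v becomes the
bipartite edge (u⁺, v⁻)); the drivers are the genes whose in-copy is
unmatched. The matching is an augmenting-path (Kuhn) algorithm whose
root order *and* neighbour preference follow a sampled node permutation:
different permutations can realise different maximum matchings while the
size — and hence the driver-set size — is provably invariant (asserted on
every run). Degenerate cases: a perfectly matched network still needs one
input, so the first node of the sampled order is designated the driver; an
edgeless network has all nodes as drivers; isolated nodes are their own
drivers. The matching is validated in the test-suite against exhaustive
enumeration on all digraphs with up to 4 nodes plus random 5- and 8-node
digraphs (the 5-node space, ~10⁶ graphs, is sampled rather than enumerated
to keep the suite fast), and against an independent Hopcroft–Karp
implementation.

The matching is resampled under 500 random node orderings (100 in the
scaled-down test studies) and genes appearing in every sampled minimal
driver set are kept as biomarker candidates.

## Signature and classifier

Candidates are filtered by a two-sided t-test on *continuous* expression
between high- and low-risk training patients at p < 0.002. Welch's
unequal-variance form is the default (the equal-variance option is exposed);
a gene with zero variance in both classes gets p = 1 by convention. The
binarised matrix exists for network construction only; the classifier
works on expression levels.

The centroid classifier stores the class means c⁺, c⁻ over the signature,
their midpoint and w = c⁺ − c⁻, and scores γ = ⟨s − c_mid, w⟩, predicting
high risk iff γ > 0; γ = 0 falls to the negative class ("otherwise"
branch). Algebraically γ = (‖s − c⁻‖² − ‖s − c⁺‖²)/2, so the sign
reproduces Euclidean nearest-centroid assignment and γ doubles as the
continuous score for ROC analysis. No feature standardisation is applied by
default (the discriminant contains none); an optional z-score flag using
training-set statistics exists for heterogeneous platforms.

## Evaluation

Predicted groups are compared by Kaplan–Meier curves and the two-group
log-rank test on metastasis-free time over *all* scored patients, including
those the 5-year rule could not label — survival analysis needs no binary
label and discarding censored patients would bias the curves. AUC is the
rank-based (Mann–Whitney) statistic of γ with averaged ranks for ties,
computed on the labelable patients; MCC is the plug-in formula with the
zero-denominator → 0 convention.

## Synthetic cohorts

The generator emulates the data model of a microarray bone-metastasis
study: genes × patients expression, clinical time/event, an undirected PPI
scaffold (preferential-attachment by default, Erdős–Rényi as a homogeneous
control), and train/test/independent splits by rounded cumulative
fractions. Everything is derived from a single integer seed and
regenerating with the same configuration is byte-identical.

Each patient receives a latent risk label R ~ Bernoulli(`baseline_risk`,
default 0.35 — a realistic 5-year bone-relapse prevalence). Every gene is a
balanced two-component Gaussian mixture (components ±1, sd 0.3), so the
median split recovers the latent component with ~0.1% error and
binarisation is never degenerate. Planted pairs are vertex-disjoint
scaffold edges with random orientation. Within the modulator's active
stratum the dependent's component is drawn conditional on R so that
P(R | A high) − P(R | A low) is exactly `effect_size`; in the inactive
stratum A is independent of R.

Three design points deserve explanation:

* **Genes are drawn conditional on risk, not risk conditional on genes.**
  The per-pair law "risk = baseline + effect within the active stratum"
  cannot hold jointly for many pairs — additive prevalence shifts of
  ~effect/4 per pair exceed probability one at the 20-pair study size. With
  the inverted construction the cohort prevalence is `baseline_risk`
  regardless of how many pairs are planted, while each pair keeps its full
  conditional contrast.
* **The dependent's two risk levels are balanced in mutual information,**
  i.e. chosen (by a root solve) so MI(q1, b) = MI(q0, b) rather than
  arithmetically centred. Conditioning on the dependent otherwise induces a
  collider association between the modulator's component and risk, and the
  reverse orientation of every planted pair would be as significant as the
  forward one; balancing cancels that signal to the curvature of the binary
  entropy (~0.02 bits versus ~0.21 forward at effect 0.5).
* **Risk-associated differential expression is a continuous mean shift,**
  applied to the planted modulators (`modulator_shift`, default
  0.8·effect) and to a random `diffexpr_frac` (default 30%) of the
  remaining genes with random sign (`diffexpr_shift`, default 0.4). Because
  expression is bimodal the shift is nearly invisible to the median split —
  it leaves the dependency network unchanged — but it reproduces the
  empirical fact that risk-associated expression in real cohorts is
  widespread and not confined to mechanistic genes. Without it the t-test
  stage would have nothing to select: the genes guaranteed to sit in every
  minimal driver set are predominantly network sources, and in a purely
  mechanistic simulation sources carry no marginal risk association.

Survival is sampled conditional on the latent label so the 5-year rule
recovers it exactly: high-risk patients get an event time from an
exponential (scale `followup_scale`/3) truncated to (0, 5]; low-risk
patients get 5 + Exponential(`followup_scale`) with a `censor_rate`
fraction censored. The generator therefore produces no excluded patients;
excluded-label handling is exercised by explicit unit tests.

What the generator does **not** emulate: microarray noise structure, batch
effects, platform merging, probe-to-gene ambiguity, correlated co-expression
modules, or hub-biased placement of dependencies. Passing tests demonstrate
the statistical machinery is correct and calibrated under the planted
model, not that the biological findings of any real cohort are reproduced.

## Test-study sizes and numerical choices

The suite runs its simulation studies at reduced sizes chosen as the
smallest that leave comfortable statistical margins: null calibration with
500 candidate pairs × 200 permutations at n = 400; power with 20 planted
pairs × 500 permutations at n = 800 over 5 seeds; end-to-end with 10
replicates (150 genes, 800 patients, 200 permutations, 100 matching runs).
Calibration bands are binomial 99% intervals; KS distance from uniform is
bounded at 0.05. Tolerances: exact identities (MI oracle, Welch oracle,
centroid algebra, matching size) at 1e-9 or tighter; Monte Carlo quantities
at 2–3 standard errors of their sampling distribution.

Known limitations: the permutation p-value is granular at 1/(n_perm+1), so
very small n_perm cannot resolve p ≪ alpha; per-pair scoring is sequential
(the seeding contract permits parallelism but none is implemented); the
log-rank statistic uses the standard chi-square(1) approximation, which is
anti-conservative for very few events; and with an empty signature the
pipeline reports no classifier metrics rather than guessing.
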