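# Methods

`cimap` implements a conditional-independence graphical analysis for
cohorts of mostly binary clinical variables — the kind of record set
assembled when auditing paediatric emergency-department presentations for
suicidal crisis: adverse childhood experiences (ACEs: abuse, neglect,
domestic violence, parental mental ill health, drug misuse, criminality,
family separation), demographics (sex, age, special educational needs,
autistic traits), clinical history (mental-health diagnoses, history of
deliberate self-harm, CAMHS contact, previous attendance), and two genuinely
categorical variables: means of self-harm (5 levels) and clinician-rated
risk to life (3 levels). Because such data are confidential, the package
pairs the analysis pipeline with a synthetic-cohort generator whose ground
truth is calibrated to the published summary statistics, so every stage is
testable end to end.

## Association statistics

All association strength is measured as plug-in mutual information in bits,

    MI(X,Y) = Σ_{x,y} p̂(x,y) log2[ p̂(x,y) / (p̂(x) p̂(y)) ],   0·log 0 ≡ 0.

Conditional MI is the stratum-weighted average Σ_z p̂(z)·MI(X,Y | Z=z);
empty strata contribute zero. Significance uses the likelihood-ratio
G-test, exploiting the algebraic identity G = 2·N·ln(2)·MI, with degrees of
freedom summed over non-empty strata as (non-zero-margin rows − 1) ×
(non-zero-margin cols − 1). Zero-margin levels are excluded from df so that
degenerate tables are flagged rather than silently over-dispersed.

The asymptotic reference is trusted only under a relaxed Cochran rule: at
least 80 % of expected counts (over non-empty margins) ≥ 1 and all ≥ 0.2.
Sparser tables fall back to a stratified permutation test with
n_perm = 9999: the observed statistic is the conditional MI and the null
shuffles the second variable within each conditioning stratum,
p = (1 + #{MI* ≥ MI_obs}) / (1 + n_perm). Shuffling within a stratum fixes
both margins and makes every consistent table multivariate-hypergeometric,
so the null is sampled directly cell-by-cell (vectorised over permutation
batches) rather than by physically permuting record arrays — identical
distribution, orders of magnitude faster. Note the ≥-tie convention puts
the whole observed atom into the tail: on a dense 2×2 at n = 500 the
permutation p sits systematically at or up to one atom (~0.02–0.07,
largest near p ≈ 1) above the continuous chi-square tail. This is the
expected conservative behaviour of a valid discrete test, not a defect.

The named follow-up comparisons use Pearson chi-square without continuity
correction (delegated to `scipy.stats.chi2_contingency`) with
φ = √(χ²/N) on 2×2 tables and Cramér's V = √(χ²/(N·(min(r,c)−1))) otherwise.
Tests are two-sided at α = 0.05 by default with no multiple-testing
correction, matching the source study's convention; Bonferroni and
Benjamini–Hochberg corrections are available behind flags.

## Structure learning

Conditioning each pairwise test on *all* other variables is infeasible for
~30 discrete variables at cohort sizes in the hundreds (strata become
exponentially sparse), so the skeleton is learned with a bounded-order,
neighbourhood-restricted scheme in the style of stable PC:

1. Start from the complete undirected graph; test every pair marginally
   and remove non-rejections.
2. For conditioning sizes 1..max_cond (default 2), test each surviving
   pair given every subset of that size drawn from the union of the two
   endpoints' neighbourhoods, *frozen at the start of the size level*.
   An edge is removed at the first non-rejection. Freezing makes the
   result invariant to variable ordering (tested); the union (rather than
   the intersection) of neighbourhoods is required for chain-induced
   distant dependencies to be separable.
3. Retained edges carry their marginal MI and the maximum p-value
   observed across all their tests.

With the Bonferroni flag, α is divided by the number of variable pairs at
every stage. The BH flag applies Benjamini–Hochberg to the marginal screen
only, because the sequential early-stopping conditional stage has no
canonical BH formulation; later conditional tests then run at raw α.

Orientation uses a total-variation asymmetry score:
score(x→y) = max over level pairs (a,b) of TV( P̂(y|x=a), P̂(y|x=b) ),
skipping level pairs with an undefined (zero-count) conditional. The edge
points toward the endpoint whose conditional distribution shifts more.
The published description of edge direction ("relative strength of
conditional probabilities") underdetermines a formula; this rule is
deterministic, documented, and isolated behind a single function so it can
be swapped. It is a heuristic: for a symmetric mechanism (e.g. a
deterministic copy) both scores tie, and ties fall back to lexicographic
order, so directions on near-symmetric edges carry little evidential
weight — the undirected skeleton and the MI weights are the robust output.

Acyclicity is enforced deterministically: edges are inserted in decreasing
MI (ties lexicographic); an edge whose preferred direction would close a
directed cycle is reversed, and if both directions close cycles it is kept
unoriented and flagged. Components of the resulting map are reported as
the undirected connected components, largest first.

## Synthetic ground truth

`paper_network()` encodes the four published clusters as a DAG with one
CPT per variable (NumPy PCG64 generator; ancestral sampling in
lexicographic topological order; fixed (network, n, seed) reproduces the
CSV byte-for-byte):

- **person-centred**: previous attendance → history of self-harm (0.11
  bits), → low mood (0.07); previous attendance and low mood → known to
  CAMHS (0.13, 0.09); CAMHS → autistic traits (0.03), anxiety (0.10),
  other diagnosis (0.06);
- **household risk**: neglect → domestic violence (0.80), → abuse (0.72),
  → social worker (0.12); family-structure links (single/step parent,
  siblings, parental separation) at the unpublished-default strength;
- **parental risk**: mental health → drug misuse; both → crime (triangle);
- **sex/means/risk**: sex → means of self-harm (0.05); means → risk
  (0.24).

Calibration works backwards from the published edge strengths:

- A binary child with one binary parent is an exact solve: with both
  margins fixed, the 2×2 joint has one free parameter, MI is monotone in
  it on the positive-association side, and Brent root-finding hits the
  target far below the 1e-6-bit contract.
- The two triangles force one two-parent node each; a collider-free
  triangle is impossible, so those CPTs use a logistic link
  P(c=1|a,b) = σ(α + β_a·a + β_b·b) whose three coefficients are solved
  (least squares to ~1e-10 residuals) so the child's marginal *and both*
  parent-child MI values are attained simultaneously.
- Categorical edges tilt the child's base distribution exponentially
  along a score matrix (females toward overdose, ideation-only toward
  low risk, overdose/suffocation toward high) and root-find the tilt;
  the induced (slightly drifted) means marginal feeds the next
  calibration downstream.

Marginal prevalences are taken from the published descriptive table where
printed (e.g. female 160/240, history of self-harm 162/240, known CAMHS
154/240). Unprinted prevalences default to 0.15 — except neglect, domestic
violence and abuse, which use 0.30: the maximum MI between two binaries of
prevalence m is H(m), and H(0.15) ≈ 0.61 bits cannot carry the published
0.80/0.72-bit edges, whereas H(0.30) ≈ 0.88 can. Unprinted edge strengths
default to 0.15 bits, strong enough to recover at the fixture sample
sizes. Every default is flagged `published: False` in the network
metadata. SEN and age are isolated nodes: the study reports no SEN–mental
health association, and no age edges are printed.

Age is an integer distribution on 8–16 built by binning a normal density
(scale 1.42) into unit bins; the location parameter is root-found so the
*discretised* distribution's mean is exactly 13.5, the reported sample
mean. (Truncating a normal located at 13.5 to the asymmetric window
[8, 16] would bias the mean to ≈ 13.37.)

## The deterministic descriptive-table cohort

`table1_fixture()` is a 240-record cohort reproducing the printed
descriptive table cell-for-cell: records are filled block-wise (previous
attenders first) with each variable assigned sequentially in declared
level order, so the fixture is deterministic and its within-stratum joint
structure is an artefact of fill order, not of calibration. Two printed
inconsistencies forced documented choices:

- every stratified sub-column sums to 57 previous attenders while the
  "All" row prints 58 (57/240 = 23.75 % also rounds to the printed 24 %);
  the fixture uses 57 so that every other cell is exact;
- a handful of printed percentages disagree with their own counts
  (66.6 % for 160/240, 10.5 % for 25/240, 31.6 % for 78/240); counts are
  treated as authoritative and percentages are recomputed half-up to 1 dp
  over the full n, which reproduces all remaining printed percentages.
- the overall age range prints (9–15) but the text and the stratified
  column give 8–16; the fixture realises 8–16 with overall mean exactly
  13.5 and previous-attender mean 781/57 = 13.70.

## What the synthetic data does and does not show

The generator matches published marginals and pairwise MI values exactly
in the population, but its higher-order structure (three-way interactions,
missingness, selection into the ED sample, COVID-era attendance shifts) is
invented: conditional independencies absent from the published map are
imposed by construction. Passing recovery tests therefore demonstrates
that the pipeline can recover a structure *of this size and strength
profile* at a given n — not that the original study's map is correct, nor
that real cohort data of n = 240 would yield a stable map. Missingness is
represented (single reserved code per variable, pairwise-complete
analyses) but the generator emits complete data.

## Problem sizes and numerical choices

Verification runs use ancestral samples of n = 100,000 for MI recovery
(sampling sd of plug-in MI there is ≲ 0.005 bits against the ±0.02
acceptance band), n = 10,000 × 20 seeds for structure recovery (with the
Bonferroni flag: at uncorrected α = 0.05 roughly 5 % of the ~180
truly-disconnected pairs would be retained by design, capping precision
near 0.7), and 1,000 replicates for type-I calibration of the conditional
test (observed ≈ 0.046–0.057 across designs at α = 0.05). Calibration
tolerances: 1e-6 bits (pairwise root-finding, achieved ~1e-12), 1e-8
(two-parent logistic solve), 1e-13 (categorical tilt bracket). Ties are
broken lexicographically everywhere; all stochastic steps take explicit
integer seeds; the RNG algorithm (PCG64) is recorded in serialised
networks so cross-language reimplementations can document divergence.

## Known limitations

- Orientation is a documented heuristic (see above); v-structure/Meek
  propagation and score-based search are deliberately out of scope.
- The G/permutation method switch creates small p-value discontinuities
  at the Cochran boundary; the method used is always recorded.
- BH correction interacts only with the marginal screen (see above).
- At the study's own n = 240 the pipeline produces maps (tested as a
  smoke contract) but edge recovery at the weaker published strengths
  (0.03–0.07 bits) is not expected at that sample size.
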