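# Methods

## Branch-centric representation

All UniFrac flavours are computed on one shared structure: for a rooted
tree with `L` leaves, every non-root node owns the branch to its parent,
giving a branch-length vector `b` and a sparse branch-by-leaf incidence
matrix `S` (`S[i, j] = 1` iff leaf `j` lies below branch `i`). A sample's
branch-mass profile is `S @ p` for its leaf-proportion vector `p`; its
presence profile is `S @ (counts > 0) > 0`. The root carries no branch;
all sums run over non-root branches. Zero-length branches are retained —
they contribute nothing to any sum, so contracting them would only change
the tree's bookkeeping, not any metric value.

Pairwise matrices are computed vectorized: the weighted, information and
ratio metrics are L1 distances between (transformed) rows of the
profiles-×-branches matrix scaled by `b`; unweighted uses
`shared = P diag(b) Pᵀ` on presence profiles with
`union = covered_i + covered_j − shared`. The per-pair functions and the
matrix path are tested against each other and against naive
set-enumeration references.

### Normalization convention

The weighted, information and ratio numerators are divided by `Σ b_i`
over **all** branches of the full input tree — not by the
abundance-dependent normalization of the original 2007 weighted UniFrac.
Consequently OTUs present in the tree but absent from the table still
count in the denominator. This matches the formulas as this toolbox
defines them and makes the three weightings directly comparable; it also
means values are not numerically comparable to QIIME/GUniFrac weighted
UniFrac output (which also prune per pair — see below).

### Information UniFrac

`I(p) = −p·log2(p)` with `0·log2(0) := 0`. Base-2 logs (bits)
throughout. The absolute value is taken on the per-branch difference —
required for symmetry and non-negativity. Note the transform is
non-injective: two distinct compositions at opposite abundance extremes
(e.g. two pure monocultures) transform to identical (zero) profiles, so
information UniFrac is a semimetric that can return 0 for different
samples; it is flagged `is_metric=False`.

### Ratio UniFrac

For branch `i` and one sample, the composition is *collapsed*: the whole
subtree below `i` becomes a single part (its branch mass) and every leaf
outside the subtree stays a separate part — `1 + (L − k_i)` parts for a
`k_i`-leaf subtree. The branch's centred mass is
`mass_i / gm(collapsed parts)`. The geometric mean is evaluated as
`exp(mean(log))`; the contract is value equality with the direct product
formula, which the oracle tests check to 1e-10. Because a single zero
part annihilates every geometric mean, the function demands strictly
positive proportions and `distance_matrix(metric="ratio")` runs zero
replacement automatically. This also requires every tree leaf to appear
in the table; build (or prune) the tree from the observed OTU set.

### Pruning

QIIME and GUniFrac reduce the tree, for every sample pair, to the OTUs
present in that pair's union, recomputing proportions on the pruned leaf
set. This is available as `prune=True` but **off by default**: each pair
is then measured on a different tree with a different denominator, and
weighted UniFrac demonstrably loses the triangle inequality (the test
suite constructs a 3-sample instance with `d(A,C) = 1 >
d(A,B) + d(B,C) ≈ 0.19`; its classical-scaling embedding shows a negative
eigenvalue). Pruned results are flagged `is_metric=False`.

## Tables, rarefaction and zero replacement

Count tables are samples × OTUs, non-negative integers; the TSV reader
auto-detects the QIIME-classic OTUs-×-samples orientation via the
`#OTU ID` header token. Rarefaction to depth `d` draws one multivariate
hypergeometric sample per row (numpy generator), processing samples in
label-sorted order from a single seeded generator: bit-reproducible,
total-conserving and element-wise dominated by the input. The default
depth is the minimum sample total. By convention rarefaction is applied
automatically **only for unweighted UniFrac** (the presence/absence
weighting assumes a common depth); `rarefy=True/False` forces either
behavior for any metric, and the stability experiment rarefies every
metric's input explicitly.

Zero replacement is Bayesian-multiplicative: each zero cell is imputed as
`0.5 / sample_total` (a uniform pseudocount of 0.5 on the counts) and the
positive parts are shrunk by one common per-sample factor so the row sums
to 1 — ratios among positive parts are exactly preserved. The exact
numerics of R's `zCompositions::cmultRepl` are *not* reproduced; the
contract (strictly positive, multiplicative, closure-preserving) is what
the ratio metric needs, and it is property-tested over random sparse
tables. For a pathological sample where the imputed mass would reach 1,
the pseudocount is shrunk to keep total imputed mass at 0.5/total.

## Ordination and stability

PCoA is classical (Torgerson) scaling: eigendecomposition of the
double-centred `−D²/2`. Negative eigenvalues (non-Euclidean input) are
reported in the spectrum but their axes dropped; variance fractions are
over positive eigenvalues only — no Lingoes/Cailliez correction, so the
printed percentages are the plain ones. Axis signs are fixed by forcing
each axis's largest-magnitude loading positive, making repeated runs and
Procrustes inputs deterministic. Procrustes overlay centres both
configurations, scales to unit Frobenius norm, solves the orthogonal
(rotation + reflection) problem, and optionally applies the optimal
isotropic scale (`scaling=False` disables it); disparity follows scipy's
standardized-sum-of-squares convention and the aligned target is returned
in the reference's frame.

The stability statistic for rarefaction instance `i` is
`V_res = |V1 − Vi| / range(V1, Vi)` per sample, where `V1`/`Vi` are the
reference and aligned instance-`i` PC1 vectors and the range is
`max − min` of the **pooled** values of both vectors (one scalar per
instance). A per-sample two-point range would make `V_res ≡ 1` whenever
the values differ at all, which carries no information; the pooled range
expresses deviation as a fraction of the ordination's width. Procrustes
alignment uses the first 2 axes by default (`n_axes` configurable) since
the overlay is of 2-D ordination plots. Instance `i` uses seed
`seed + i`, so any single rarefaction is auditable. Migration flags
record PC1 sign flips between instances 1 and 2.

Confidence ellipses over the per-instance (max, median) clouds are
bivariate-normal: sample mean and covariance, semi-axes
`sqrt(χ²₂(level)·eigenvalue)`; singular covariance is flagged degenerate.
Monte-Carlo coverage is verified at n = 10,000.

## Synthetic study designs

The generators produce every dataset class the experiments need; all are
deterministic given (spec, seed).

**Trees** are random sequential-joining (coalescent-style) binary
topologies with exponential branch lengths (mean 0.1). Long isolated
branches — the structure that amplifies rarefaction flips — are injected
by stretching randomly chosen pendant edges (default 10 edges at 10×).
No claim is made that this matches real 16S tree shape; only the
long-branch property matters for the phenomena studied.

**Single-site ("uniform") design** — 60 samples, 554 OTUs, depths
log-uniform in [659, 17176] with the bounds anchored, a sorted
lognormal(σ=2) rank-abundance centre. Each sample's composition is drawn
from a Dirichlet around the centre with concentration 50, in the range
implied by published Dirichlet-multinomial fits to human-body-site data
(overdispersion θ ≈ 0.01–0.05 ⇒ concentration ≈ 20–100): real single-site
cohorts are distinct individuals, so inter-sample compositional
dispersion exists even with no group structure. `dispersion=inf` gives
the limiting design where all samples share literally one composition
(useful for law-of-large-numbers checks, but degenerate for the stability
comparison: every metric's PC1 is then pure noise). The stability
experiment filters OTUs with <100 total counts and rarefies to the
minimum depth, matching standard practice.

**Two-group design** — group compositions `(1−e)·base + e·clade_mass`
with the clade masses on the two disjoint clades below the root; `e=0`
reduces to the single-site design.

**Near-monoculture design** — a packaged synthetic 115-OTU template
(50,000 counts, 97% dominant, Zipf(s=2) remainder whose top subdominants
reach ~1–2%, about half the OTUs absent). Each simulated sample is a
uniform random permutation of the template's counts with the maximal
count then swapped into the group's dominant OTU: three groups × 20
samples, every sample an exact multiset copy of the template. The Zipf
tail matters: subdominants at ~1–2% carry surprisal weight exceeding the
dominant's (`I(0.97) ≈ 0.04` vs `I(0.015) ≈ 0.09`), which is precisely
the regime where information UniFrac loses the monoculture identity while
weighted/ratio/Bray-Curtis keep it.

**Long-branch flip scenario** — an 8-OTU tree whose flagged pendant
branch is ≥5× the median pendant length, and a two-sample table (totals
1075 and 221) where the flagged OTU has 5 counts in the deep sample: the
hypergeometric probability of rarefying it to zero at depth 221 is 0.316,
asserted to lie in (0.2, 0.8) so both outcomes occur routinely. (A count
of 7, as in the packaged worked example, gives 0.1997 — marginally too
deterministic for the demonstration.)

## What the generators do not emulate

Sequencing error, chimeras, PCR primer bias, true phylogenetic signal in
abundances (abundances are assigned to leaves independently of tree
position, except the two-group clade construction), and real tree shape.
Passing tests therefore demonstrate the *mechanisms* — rarefaction-flip
sensitivity, extreme-abundance blindness, pruning-induced metric failure
— not calibrated magnitudes on any particular real cohort; published
variance-explained percentages from real data are not reproduced here.

## Numerical choices and degenerate inputs

- Proportion sums checked to 1e-6; proportion-table row sums to 1e-9.
- `0·log2(0) := 0` wherever a surprisal is evaluated.
- Midpoint rooting conserves total branch length; the two-leaf case is
  handled directly (the single path is split in half); an all-zero-length
  tree is rejected (midpoint undefined). Ties between equal diameters
  resolve by the library's deterministic traversal order.
- Missing Newick branch lengths parse as 0.0 with a warning; internal
  node labels are ignored; duplicate leaf labels are a parse error.
- PCoA eigenvalue positivity cutoff: `max(|λ|, 1)·1e-12`; an all-zero
  matrix returns one all-zero axis.
- Triangle-inequality checks in tests use tolerance 1e-9.
- Problem sizes: the stability experiment runs 60 samples × 554 OTUs ×
  100 rarefactions × 5 metrics (seconds, vectorized); oracle-equivalence
  sweeps use 100 random ≤10-leaf instances at 1e-10.

## Known limitations

- Pruned-mode matrices are computed per pair by tree shearing, O(n²)
  shears — fine for the small instances it exists to demonstrate, slow
  for large cohorts.
- Ratio UniFrac values are unbounded above (they scale with how far
  masses sit from the geometric-mean baseline); only Bray-Curtis and
  unweighted UniFrac live in [0, 1].
- Zero replacement is one member of the multiplicative family, not a
  reimplementation of any specific R routine.
- BIOM import is not included; tables are TSV.
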