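# Methods

## Measures

### Association measures

All coefficients consume an N × N correlation matrix with unit diagonal,
entries in [−1, 1], symmetric to 1e−8 (validated on construction and on
read; positive semi-definiteness is checked with a warn-only threshold of
−1e−8·N on the smallest eigenvalue, because round-tripping matrices through
delimited text perturbs eigenvalues at that scale).

The three-way partial correlation of j and ℓ given a single node i is

    ρ_partial(j,ℓ|i) = (ρ(j,ℓ) − ρ(i,j)ρ(i,ℓ)) / √((1−ρ(i,j)²)(1−ρ(i,ℓ)²)).

Conditioning on a *single* node, rather than on all N−2 others, keeps the
measure local, exactly as the conventional clustering coefficients are
local. The full partial correlation matrix (precision-based,
−P_ij/√(P_ii P_jj)) is provided separately as a benchmark connectivity
measure; it refuses inputs with condition number above 1e12 — shrinkage or
regularised estimation is deliberately out of scope.

The Gaussian partial mutual information is evaluated directly from the
three-log entropy expression

    I(X_j,X_ℓ|X_i) = ½[ln(1−ρ(i,j)²) + ln(1−ρ(i,ℓ)²) − ln det R₃],
    det R₃ = 1 − ρ(i,j)² − ρ(i,ℓ)² − ρ(j,ℓ)² + 2ρ(i,j)ρ(i,ℓ)ρ(j,ℓ),

in natural logarithms (nats). The algebraically equivalent identity
I = −½ ln(1 − ρ_partial²) is used only by the test oracles, so the two
routes check each other.

Degeneracy guard: whenever 1−ρ² or det R₃ falls at or below ε = 1e−12
(configurable) for a triple that would contribute weight, a
degenerate-triple error naming the node is raised rather than returning
NaN/∞. Triples whose weight |ρ(i,j)ρ(i,ℓ)| is zero contribute nothing to
numerator or denominator and are never an error, even if degenerate.

### Clustering coefficients for correlation matrices

    C_i^cor,A = Σ_{j<ℓ; j,ℓ≠i} |ρ(i,j)ρ(i,ℓ) ρ_partial(j,ℓ|i)| / Σ |ρ(i,j)ρ(i,ℓ)|
    C_i^cor,M = Σ_{j<ℓ; j,ℓ≠i} |ρ(i,j)ρ(i,ℓ)| I(X_j,X_ℓ|X_i) / [(1+ln 2π)/2 · Σ |ρ(i,j)ρ(i,ℓ)|]

A node is *undefined* when its (possibly sign-filtered) denominator is zero;
undefined nodes are excluded from — never zero-filled into — the global
average, and their count is reported. Zero-filling would bias global values
downward on sparse matrices. If no node is defined the global coefficient is
an error, mirroring the removal of subjects whose matrices admit no
triangle.

C_i^cor,A is bounded in [0, 1] because |ρ_partial| ≤ 1 whenever the inputs
form a valid correlation matrix. C_i^cor,M's normaliser (1+ln 2π)/2 ≈ 1.419
is the nominal upper scale, but I = −½ln(1−ρ_p²) exceeds it once
|ρ_p| ≳ 0.973, so the value can exceed 1 on near-singular matrices. We
compute it as defined, never clip, and emit a warning when a local value
exceeds 1 — a documented deviation from the nominal [0, 1] claim.

Sign filters use strict inequalities (> 0 for positive triangles, < 0 for
negative); zero correlations belong to neither restricted variant. The
admitted positive- and negative-triple sets are disjoint subsets of the
unrestricted set.

### Conventional comparators

Unweighted: edges are laid where ρ(i,j) ≥ θ (inclusive), or — with the
edge-density rule — exactly ⌊d·N(N−1)/2⌋ edges are kept, taking the
largest off-diagonal values with descending-value, lexicographic-(i,j)
tie-break. The tie-break makes density thresholding a deterministic
function of the matrix; nodes with degree ≤ 1 are undefined.

Weighted: w_ij = ρ(i,j) if ρ(i,j) > 0 else 0, zero diagonal; the adjacency
inside the Barrat/Onnela/Zhang formulas is a_ij = 1 iff w_ij > 0 (weight
positivity, not any θ). Onnela's and Zhang's max-normaliser is recomputed
per matrix — the formulas are written per network, and a cohort-fixed
normaliser would leak information across inputs. Definedness: Barrat needs
k_i ≥ 2 and s_i > 0; Onnela k_i ≥ 2 (an all-zero network short-circuits to
all-undefined); Zhang a positive denominator Σ_{j≠ℓ} w_ij w_iℓ. On binary
weights all three reduce exactly to the unweighted coefficient, and Onnela
and Zhang are invariant under uniform weight rescaling — these reductions
are enforced by tests.

### Connectivity summaries

s is the mean of ρ over all node pairs, s⁺ the mean over pairs with
ρ ≥ 0 (nonnegative); the nodal positive strength s_i⁺ sums entries with
ρ > 0 (strictly positive). The two conventions are intentionally not
harmonised — each is implemented as defined where it is used — and the
asymmetry is immaterial in practice because exact zeros have probability
zero. s̃_i = s_i/(N−1) ∈ [−1, 1], and s equals the mean of s̃_i.

## Null models

### White noise

N independent standard-normal series of length T, correlated sample-wise.
Off-diagonal entries then have sd ≈ 1/√(T−1), and the three-way partial
correlations of independent signals are asymptotically half-normal with
E|ρ_partial| ≈ √(2/π(T−3)) — 0.0568 at T = 200 — which is the mechanism
behind the chance level of C^cor,A (≈ 0.057 at N = 30, T = 200; C^cor,M's
chance level ≈ ½E[ρ_p²]/1.419 ≈ 0.002). Defaults N = 30, T = 200 with 138
replicates define the chance-level study the acceptance script reruns.

### H-Q-S random covariance

Given a reference covariance, the preserved moments are μ_on (mean
diagonal), μ_off (mean off-diagonal) and σ²_off (population variance of the
off-diagonal; the population/sample distinction is O(1/N²) and we fix the
population convention, likewise denominator-T covariance on the time-series
path). The latent sample length is t̄_max = max(2, ⌊(μ_on²−μ_off²)/σ²_off⌋),
and cov = X Xᵀ with X an N × t̄_max matrix of iid normals with

    mean √(μ_off/t̄_max),
    variance −μ_off/t̄_max + √(μ_off²/t̄_max² + σ²_off/t̄_max).

This parameterization gives exactly E[cov_ij] = μ_off, Var[cov_ij] = σ²_off
and E[cov_ii] = √(μ_off² + t̄_max σ²_off), which equals μ_on whenever the
floor truncates nothing. A radical-free variant of the latent mean/variance
is exposed behind `literal_parameterization=True` for auditing; it
preserves no moment and is infeasible (negative variance) for most moment
settings, which is why it is not the default. The algorithm requires
μ_off > 0 and σ²_off > 0 and raises a precondition error otherwise (the
standard practice is to drop such reference matrices). Only the base
algorithm is implemented — no fine-tuned heuristic variants. One integer
seed governs one matrix; replicate batches spawn child seeds from a
`SeedSequence`.

The Gram construction makes every output exactly positive semi-definite;
normalisation to a correlation matrix divides by √(cov_ii cov_jj).

## Synthetic fixtures

Structured series are latent-factor constructions,
x = √c·factor + √(1−c)·noise with coupling c ∈ (0, 1), so every population
correlation is known in closed form and downstream expectations are
derivable without running the implementation:

* `common_driver` — node 0 *is* the factor; ρ(hub, j) = √c and
  ρ(j, ℓ) = c = ρ(hub,j)ρ(hub,ℓ) exactly, so peripheral partial
  correlations given the hub vanish in the population and the hub's
  C^cor,A is pure sampling noise (→ 0 as T grows) while conventional
  weighted coefficients stay high.
* `direct_triad` — three designated nodes share a factor; within-triad
  ρ = c and ρ_partial given the third member is c/(1+c) > 0.
* `block` — disjoint groups share group factors; within-group ρ = c,
  between-group 0.

The generator emulates the second-order structure of functional-connectivity
data only: Gaussian margins, no temporal autocorrelation, no hemodynamics,
no measurement artefacts. All coefficients are functions of the correlation
matrix alone, so this is sufficient for their validation; passing tests say
nothing about preprocessing-induced artefacts in real recordings.

## Study conditions used by the checks

Problem sizes are chosen to resolve each effect while keeping the whole
suite fast: chance-level runs use the full 138 × (N = 30, T = 200) design;
oracle equivalence uses 100 random matrices with N ≤ 8 (brute-force triple
enumeration is cubic); H-Q-S moment recovery uses 2,000 replicates for each
of three moment settings with dyadic-rational moments, so
(μ_on²−μ_off²)/σ²_off is an exact machine integer and the floor introduces
no truncation bias into the μ_on check; the confound contrast uses 100
H-Q-S matrices from (μ_on, μ_off, σ²_off) = (1, 0.05, 0.09), t̄_max = 11 —
a weak-mean-coupling regime representative of globally regressed functional
covariances, in which conventional weighted coefficients correlate
positively with normalised strength across nodes while C^cor,A and C^cor,M
stay near-orthogonal to it; discrimination uses T = 10,000 and 20 seeds so
the hub's sampling noise (≈ √(2/πT) ≈ 0.008) is well below the triad
signal c/(1+c) = 1/3.

## Numerical and design choices

* Pearson correlations via `numpy.corrcoef`, symmetrised, clipped to
  [−1, 1], exact unit diagonal.
* All coefficient kernels are vectorised per node (outer products over the
  N−1 neighbours); the O(N³) Python-loop implementations live only in the
  test oracles.
* Tables are tidy long format (node × coefficient), with a wide pivot
  behind a flag; matrices are full-square comma-delimited text written with
  17 significant digits, so write/read round-trips are bit-faithful.
* Batch runs write a JSON manifest (config, version, failure list);
  re-running an identical manifest reproduces outputs byte-for-byte.

## Known limitations

* No shrinkage/regularised partial-correlation estimation; ill-conditioned
  inputs are an error, not a warning.
* Negative weights are handled only by discarding (weighted comparators) or
  by the sign-filtered variants; no signed-network clustering scheme is
  implemented.
* C^cor,M can exceed 1 on near-singular inputs (see above).
* The time-series path computes correlations on the series as supplied; no
  detrending or filtering is performed in-package.
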