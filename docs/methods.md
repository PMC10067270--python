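# Methods

## Data model

A landscape is a map from genotypes over `N` named binary loci to a finite
scalar fitness in caller-defined units.  Storage and file formats use the
{0, 1} presence encoding throughout; the ±1 encoding exists only inside
the Walsh module (`x = 2·presence − 1`).  Keeping a single canonical
encoding avoids the sign errors that arise when the two conventions mix:
on the {0,1} scale an additive effect δ_i is the fitness change of adding
the mutation, while on the ±1 scale the corresponding coefficient is
f_i ≈ δ_i/2 plus interaction corrections — the package never converts by
formula, it transforms the landscape and reads the coefficients off.

Incomplete landscapes are first-class.  Every background-averaged
quantity uses only the terms whose genotypes are measured and reports the
count used (`n_used`, `n_epistasis_terms`, `n_effect_terms`); fits require
at least 3 points.  Landscape files are written at full `%.17g` precision
so a save/load round trip is bit-exact; derived analysis tables default to
6 significant digits with a `--full-precision` switch.

## Per-mutation regression

For focal mutation i the scatter has one point per background in B(i):
(F_B, ΔF_i(B)) with ΔF_i = F_{B+i} − F_B, uniform weight per background.
The fit is ordinary least squares; R² is the squared Pearson correlation
(identical to the coefficient of determination for simple OLS).

Degenerate scatters are flagged, not fatal:

* zero variance in F_B → no slope (NaN), `degenerate=True`;
* constant ΔF → slope exactly 0, R² reported as 0 by convention,
  `degenerate=True`.  "Constant" is detected as a ΔF spread at or below
  `1e−12·max(1, |ΔF|_max)`: an additive landscape built in floating point
  carries ~1e−16 jitter in its effects, and without the guard that jitter
  can masquerade as a significant trend.

Pattern classification: a mutation is called beneficial (deleterious) when
every ΔF is positive (negative), else mixed-sign; the slope is called
nonzero when the standard two-sided t-test on the OLS slope rejects at a
caller-supplied `alpha` (default 0.05, logged in output headers; no
flatness criterion is standard, so the test-based rule is this package's
choice).  Beneficial + negative slope → diminishing returns; beneficial +
positive → increasing returns; deleterious + negative → increasing costs;
deleterious + positive → decreasing costs; non-rejected or degenerate →
flat.  No multiple-testing correction is applied across mutations by
default, since classification is per-mutation; callers can Bonferroni by
passing `alpha / N`.

## Walsh expansion

Coefficients are taken in the uniform-measure orthonormal basis on
{−1, +1}^N: each coefficient is the mean over all 2^N genotypes of F times
the corresponding sign character.  This normalisation is the one that
makes the identities

    f_ij = ⟨ε_ij⟩ / 4 ,      f_j − f_ij = ⟨δF_j⟩_B(i) / 2

exact on pairwise-truncated landscapes (any other scaling breaks them),
makes the transform involutive, and yields Parseval's identity
Var(F) = Σ_{S≠∅} f_S².  The identities are asserted in tests only on
pairwise-truncated landscapes; for landscapes with higher-order terms the
background averages absorb those terms and the identities are
approximations by construction.

The exact transform requires a complete landscape and is computed by a
fast butterfly (O(N·2^N)); the O(4^N) direct sign-sum is retained as the
independent oracle and cross-checked in the test suite.  For incomplete
landscapes an explicit least-squares mode estimates coefficients up to
`max_order` by minimising squared reconstruction error over measured
genotypes; its output is flagged `estimated` and requires at least as many
genotypes as coefficients.

## Slope decomposition

`averages` mode computes ⟨ε_ij⟩ over every background lacking both loci
with all four corners measured, and ⟨δF_j⟩_B(i) over every background
lacking both the focal locus and j with both B and B+j measured —
averaging over backgrounds that lack *both* loci is the only reading under
which ΔF_j is well-defined on B(i), and it is validated numerically
against 2(f_j − f_ij).  `walsh` mode reads the same quantities off the
order-2 Walsh coefficients; the two agree exactly on complete
pairwise-only landscapes and are compared in the test suite.  The
predicted intercept a_i = ⟨ΔF⟩ − b_i·⟨F_B⟩ takes both averages over the
focal mutation's own scatter, which makes it the OLS intercept whenever
b_i is the OLS slope.

Exactness domain: when every interaction involves the focal locus (no
background–background epistasis), the prediction equals the OLS slope at
machine precision; with background–background interactions the error
shrinks with the interaction-to-additive magnitude ratio.  Both properties
are tested.

A partner with ⟨δF_j⟩ = 0 but ⟨ε_ij⟩ ≠ 0 has β_ij undefined: it is
reported with β = NaN and ω = 0, and the sum form of the slope — which
stays well-defined — is authoritative.  If *all* ⟨δF_j⟩ vanish the slope
is undefined and the decomposition is flagged degenerate.  Partners with
no computable term on an incomplete landscape are dropped from the sums
(their absence is visible through the partner list).

## Simulators

Simulator parameters (baseline, δ_i, ε_ij) live on the {0,1} presence
scale.  All four generators produce complete landscapes; the
house-of-cards generator is the only stochastic one and carries its own
seed (one `numpy.random.default_rng` per simulation), so identical specs
give bit-identical landscapes.

* **additive** — F(g) = baseline + Σ δ_i·presence_i.  Default fixture
  effects (+0.3, +0.2, +0.1, −0.1, −0.2, −0.3) realise three beneficial
  and three deleterious mutations; the magnitudes are arbitrary since any
  additive landscape is flat.
* **house-of-cards** — 2^N iid Normal(mean 1, sd 0.2) draws by default,
  the maximally rugged regime.  Only the normal distribution is in scope.
* **pairwise** — additive plus ε_ij·presence_i·presence_j over a sparse
  pair set; with an empty set it equals the additive generator
  elementwise.
* **latent** — λ(g) additive, F = exp(λ) (convex) or F = 1 − exp(−λ)
  (concave saturating).  Exponential transforms give exactly linear
  scatters: ΔF = (e^{δλ} − 1)·F_B for the convex case and
  ΔF = (1 − e^{−δλ})·(1 − F_B) for the concave one; the closed forms are
  exposed as `latent_closed_form_slope` and matched by simulated OLS to
  machine precision.

What the generators emulate — and do not.  They produce noise-free,
exhaustively measured landscapes with independent, homogeneous
interaction structure.  Real data add measurement error (which itself
biases ΔF-vs-F_B slopes negative), incomplete and non-random genotype
sampling, selection-biased mutation panels, and possibly regional
structure.  Passing tests therefore demonstrate correctness of the
estimators and the internal consistency of the theory on its own model
classes, not robustness to those empirical complications.

## Problem sizes and determinism

The regression-to-the-mean check uses 500 replicate 6-locus
house-of-cards landscapes (3000 fits, a few seconds); the Walsh round
trip sweeps 1000 random landscapes up to N = 10 with periodic
direct-oracle spot checks; identity suites use 100 random pairwise
landscapes with N = 4–8.  Every stochastic test and the acceptance script
derive all child seeds from one master seed.

## Known limitations

* Slope predictions truncate at pairwise epistasis; landscapes dominated
  by third- and higher-order interactions will show systematic
  prediction–OLS gaps (the HoC regime is the extreme case).
* The residual structure around the global-epistasis line is not
  modelled, and no nonlinear (non-OLS) scatter fits are provided.
* Loci are strictly biallelic; no sequence-level handling, no measurement
  error model, no fitness-unit conversions.
* The least-squares coefficient estimator for incomplete landscapes is a
  plain unregularised fit; heavily undersampled landscapes need more
  structure than it assumes.

## Analysing an empirical landscape

Any published combinatorially complete fitness table (for example a
five-mutation bacterial landscape with measured relative fitness for all
32 genotypes) can be analysed by writing it in the wide TSV dialect —
header = locus names + `fitness`, one 0/1 row per genotype — and running
`epiland fit` and `epiland decompose --focal all` on it.  The package is
unit-agnostic: use whatever fitness scale the source reports.
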