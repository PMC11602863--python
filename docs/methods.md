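# Methods

## The problem

Phenoxyalkanoic acid herbicides (PAAHs: 2,4-D, MCPA, dichlorprop-P,
mecoprop-P, 2,4-DB, MCPB) are monoprotic carboxylic acids with pKa between
roughly 2.7 and 4.9.  In mineral soils their solid–solution distribution
coefficient Kd (mL/g) changes by an order of magnitude over the agronomic pH
range, because both the herbicide speciation and the population of active
sorption sites are pH-dependent.  `phsorb` implements a family of additive,
intercept-free Kd models whose predictors are soil constituents weighted by
speciation factors, together with the supporting constructions (pore
accessibility of fulvic acids, potential-acidity decomposition), the
penalized-regression fitting machinery, single-sorbent adsorption-edge fits,
and a synthetic-data generator that makes every stage testable without the
original laboratory tables.

## Speciation and site fractions

The neutral fraction of a monoprotic acid is Φₙ = 1/(1 + 10^(pH−pKa)) and the
anionic fraction Φₐₙ = 1 − Φₙ.  Sorbent surfaces carry their own
pH-dependent site populations, described by the generalised logistic
f = 1/(1 + 10^((pH−pKa_site)/η)); read as f_n for acidic organic-matter
groups (conventional defaults pKa_site = 5, η = 2) or as f_p, the
positively-charged site fraction of amine groups and Al/Fe oxyhydroxide
surfaces.  η = 1 reduces the site logistic to the Henderson–Hasselbalch
form; η → 0 approaches a step at pKa_site.  The exponent can reach ±50 for
small η, so the logistic is evaluated through `scipy.special.expit` and the
result clamped to [0, 1].  pH always means the measured suspension pH of the
individual soil×experiment record, never an assumed soil constant.

## Pore accessibility of fulvic acids

Fulvic acids coat the internal surface of soil pores; PAAH molecules
(≈ 0.9–1.2 nm long) cannot reach the coating inside the narrowest pores.
Two allocations of the bulk FA content (mg OC/g) over BJH pore-size classes
produce the accessible-content predictors:

* **constant thickness** ("C"): content above a radius cutoff is
  proportional to the BJH surface area above the cutoff (FA_>3.5C uses a
  3.5 nm cutoff);
* **logistic** ("L"): surface density S(r) = S_min + S_max·2^(−(r/r_half)²),
  a lognormal-like decay concentrating FA in fine pores.  With the ratio
  S_max/S_min and r_half fixed on small grids (ratios 1.5–10.5, r_half
  2.0–5.0 nm; headline values 6 and 3.5 nm), the single free scale S_min has
  the closed-form mass-balance solution
  S_min = FA / Σᵢ areaᵢ(1 + ratio·wᵢ), wᵢ = 2^(−(rᵢ/r_half)²).
  FA_>2.5L sums class contents with lower bound ≥ 2.5 nm.

Each class is represented by its lower-bound radius; bins are half-open and
the ≥30 nm class is the terminal open class.  Mass is conserved exactly, and
the constant-thickness allocation is the ratio → 0 limit of the logistic one
(verified numerically at ratio = 1e−9).  The surface-density reading (mg/m²
times class area) is the only one in which the fitted total carries the unit
mg/g and can equal the measured FA content; the tests pin the closed form
against a brute-force one-dimensional scan of the squared mass-balance
error.  HA analogues are available through the same operations but are not
part of the default pipelines (they did not improve prediction).

## Potential-acidity decomposition

Potential acidity is titrated in BaCl₂–triethanolamine buffered at pH 8.2,
so the titratable-site count at suspension pH scales with (8.2 − pH).  The
Al and H components are modelled as non-negative, intercept-free linear
combinations of (8.2 − pH)-scaled constituents — accessible FA, sand and
humin for Al(PA); silt+clay, Tamm-extractable Al and Fe, and accessible FA
for H(PA).  Reference coefficient sets (Lasso variants with FA_>2.5L or
FA_>3.5C, and a Ridge variant retaining HA) are shipped as constants; the
generator uses them as its ground truth, and refits on generated data must
recover them.  Models are fitted without intercept because the acidity
components vanish at the reference pH by construction of the method, and
coefficients are constrained non-negative because negative acidity
contributions are physically meaningless.

## Soil-scale Kd models

Design-matrix columns are soil variables multiplied by Φₙ or Φₐₙ at each
sample's pH, optionally by f_p(η, pKa), optionally by (8.2 − pH).  The
screening ladder fits, for every herbicide, a sequence of structures — OC
only; FA/HA/HU; OC plus acidity components; fractions plus acidity; the
empirical model with FA_>3.5C; the empirical model with FA_>2.5L; the
mechanistic model — and reports the mean (adjusted) R² across herbicides
with equal weights, the model-comparison statistic.

The empirical model:
Kd = Φₙ·FA_X·κ + Φₐₙ·(HA·κ + HU·κ + Al(PA)·κ + H(PA)·κ).

The mechanistic model replaces the acidity components with their sources:
Kd = Φₙ·FA_>2.5L·κ_FA.n + Φₐₙ·[HA·κ_HA.an + HU·κ_HU.an
     + (FA_>2.5L·κ_FA.an + Al(T)·κ_Al.an)·f_p(η_Al, pKa_Al)
     + Fe(T)·κ_Fe.an·f_p(η_Fe, pKa_Fe)].

One pKa governs the Al³⁺-bridge sites shared by accessible FA and Tamm Al;
a separate pair governs Fe oxyhydroxides.  The Fe term sits inside the
anionic bracket: only anionic PAAH forms sorb on Fe-oxyhydroxide sites, and
the coefficient is an anionic capacity — the additive structure makes the
placement consequential only through the Φₐₙ weight, and the anionic reading
is the physically coherent one.  The Φₐₙ·f_p product creates the
characteristic mid-pH adsorption window for anion-bridge terms: zero at both
pH extremes with a single interior maximum when pKa_site > pKa of the
herbicide (asserted on a dense pH grid).

All Kd models are intercept-free (zero sorbent implies zero sorption) with
non-negative κ (capacities).  The (η, pKa) pair of the bridge sites is
found by a nested grid search maximizing the mean adjusted R² over
herbicides, with deterministic tie-breaks (larger η, then smaller pKa).
Default grids: η ∈ {0.1, 0.2, 0.5, 1, 1.5, 2}; pKa over [2, 8].  The pKa
step is configurable; library default 0.05, and the acceptance study uses a
0.25 step over a bracketing subrange as its default search resolution.

Simplified variants serve narrow pH ranges: for soils with pH ≤ 5.6,
accessible FA carries the neutral (and, mechanistically, anionic) sorption
with metal terms under a sharp site factor f_p(0.1; 4.6); for pH ≥ 6.6, HA,
HU and FA_>2.5L·f_p(0.1; 7.3) describe the remaining anionic sorption.

## Penalized fitting

Lasso and Ridge fits use scikit-learn's coordinate-descent/LBFGS solvers
with `positive=True` and `fit_intercept=False` inside a seeded K-fold
cross-validation loop (default tenfold; fivefold available).  The λ grid is
log-spaced over four decades below the data-driven maximum (smallest Lasso λ
zeroing all coefficients) and always includes λ = 0, solved by non-negative
least squares, so CV may select no shrinkage — on noise-free data it does,
making recovery exact.  Predictors are scaled by their standard deviation
(no centering, which would break the intercept-free structure) and
coefficients back-transformed; reported λ values therefore live on the
scaled-predictor scale and are not directly comparable to values from other
software.  Standardized coefficients are coef·sd(x)/sd(y), invariant to
unit rescaling.  Adjusted R² uses 1 − (1−R²)(n−1)/(n−p−1) with p the number
of nonzero coefficients.  Zero-variance predictors are dropped with a
warning; an identically-zero target returns the zero coefficient vector.

Kendall τ_b (tie-corrected, via `scipy.stats.kendalltau`) screens
speciation-weighted predictors against Kd; rank correlation is used because
the soil variables are mostly non-normal.  The tests verify τ against an
exhaustive O(n²) pair-enumeration oracle up to n = 50.

## Single-sorbent adsorption edges

Five additive forms describe Kd(pH) for an isolated sorbent at content X:
neutral-only, neutral+anionic, neutral+anionic·f_p, neutral plus two anionic
site types (pH-independent κ_an1 and pH-dependent κ_an2·f_p), and
anionic·f_p only (the oxide form).  For fixed (η, pKa) every form is linear
in the κ's, so fitting concentrates the NNLS solution over the two site
parameters, optimized by Nelder–Mead on (log η, pKa) from a 3×3 multi-start
grid (η ∈ {0.2, 1, 2} × pKa ∈ {3, 5, 7}) — the concentrated objective is
multimodal.  Forms with f_p require at least four distinct pH values.
`compare_forms` ranks candidates by adjusted R², ties toward fewer
parameters.  Al³⁺ loading of a humic fraction is a treatment label on the
dataset, never a model term; each loading is fitted separately.

## Synthetic-data generator

The generator emulates the study design: 6 profiles × 3 horizons (18
samples); suspension pH evenly spread over 4.2–7.7 with a seeded jitter and
shuffle (guaranteeing span ≥ [4.5, 7.5] so the anionic and f_p terms are all
exercised); lognormal OC around topsoil/subsoil medians of 11.0/1.3 mg/g,
sorted to decrease with depth within a profile; a Dirichlet humic partition
centred on FA:HA:HU ≈ 20:25:55 with FA+HA+HU = OC exactly; sandy Dirichlet
textures summing to 100; lognormal Tamm Al (median 0.6 g/kg) and Fe (median
1.5 g/kg); and Dirichlet pore-surface fractions centred inside the observed
class ranges with the finest micropore classes holding most of the BJH
area.  Lognormal and Dirichlet families were chosen for positivity and
realistic skew; no distributional forms were prescribed, and every
parameter is exposed in `GeneratorConfig`.  Acidity components come from
the reference models (exact round-trip at zero perturbation).  Kd noise is
multiplicative lognormal with mean 1 (Kd is positive and analytical error
scales with concentration).  Everything is reproducible from (config,
seed).

The generator does **not** emulate: spatial correlation between profiles,
measurement error in the soil properties themselves, concentration
dependence (Freundlich nonlinearity), ionic-strength effects, or multiple
herbicides competing for sites.  Passing recovery tests therefore show that
the estimation machinery is unbiased and stable under the assumed noise
model — not that the model family is correct for any particular real soil.

## Numerical choices and problem sizes

Overflow-safe logistics; closed-form pore allocation (no iterative fit);
λ = 0 handled by NNLS rather than a zero-penalty coordinate descent; CV fold
assignment by seeded shuffle, recorded in every fit; deterministic
tie-breaks in both grid searches.  The recovery studies use the 18-soil
design at 5% multiplicative noise with 50 seeds — the pooled median
relative error of the recovered capacities stays near 10%, while
deliberately weak terms (the Fe-oxyhydroxide capacity, whose f_p is below
0.03 across the soils' pH range) are not individually identifiable at this
noise level; on pH-filtered subsets (7 samples) the two metal-site columns
share the same sharp f_p factor and only their combined contribution is
identifiable.  These are properties of the study design, not of the
estimator.

## Known limitations

* Herbicide pKa values shipped with the package are placeholder literature
  values (`io.DEFAULT_HERBICIDES`); users with measured constants should
  supply their own config.
* Reported λ_optimal is scale-dependent (see above).
* Monoprotic speciation only; no activity/ionic-strength corrections; no
  sorption kinetics or temperature dependence.
* Kd values below the OECD-106 acceptability range are used as-is (a
  warning is emitted); there is no censoring model.
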