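# Methods

This note documents the models implemented in `soilrisk`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter for reproducibility.

## Synthetic surveys

The generator draws datasets from the non-negative source-mixing model

    X = G F,   observed as  x_ij = (GF)_ij · ε_ij,

with `G` (samples × sources) the source activities, `F` (sources ×
elements) the source signatures in mg/kg per unit activity, and `ε_ij`
multiplicative lognormal noise with unit mean and a per-element
coefficient of variation (CV). Multiplicative noise was chosen because
concentrations are strictly positive and polluted-site marginals show
CVs at or above 100%; additive Gaussian noise would produce negative
values. Cells falling below the per-element method detection limit (MDL)
are flagged censored and reported at a substitute (MDL/2 by default —
the same 0.5·MDL constant that enters the PMF uncertainty equation).

Defaults emulate a 30-sample, 12-element (As, Cd, Co, Cr, Cu, Fe, Mn,
Ni, Pb, Sb, Zn, Hg) survey of a mining/smelting-impacted area with five
sources: an As-dominated atmospheric source, an Sb–Hg–Pb smelting
source, two geogenic (Fe–Mn–Cr–Ni) sources and a Pb–Cd–Zn source.
Source activities are lognormal with unit mean and CV 1.0 (gamma and
constant laws are configurable); this activity variability — not the 10%
measurement noise — is what produces the heavy right tails. Element
scales follow the polluted-site averages for As/Pb/Sb (85, 411, 3.1
mg/kg) and common upper-crust levels for the rest. Clay and
organic-matter percentages are scaled Beta draws (means ≈ 25% and 10%),
bounded in [0, 100].

`emulate_study_marginals` produces single-element lognormal draws
moment-matched to a printed (mean, SD) pair via
`σ² = ln(1 + cv²)`, `μ = ln(mean) − σ²/2`, for emulating marginals whose
only published summary is a moment pair.

**What the generator does not emulate:** spatial autocorrelation (the
x/y coordinates are uniform noise), inter-element correlation beyond
what the mixing model induces, analytical drift or batch effects, and
the exact site-specific distribution of any real survey. Passing
recovery tests therefore demonstrates correctness of the algorithms
under the stated generating law, not performance on any particular field
dataset.

## Pollution indices

Target (SW) and intervention (IW) values are corrected for soil
properties. The default "standard" dialect applies the multiplicative
Dutch correction

    (SW,IW)_b = (SW,IW) · (A + B·clay + C·om) / (A + 25B + 10C),

which is exact for the reference soil (25% clay, 10% OM). A "literal"
dialect evaluating `((SW,IW)·A + B·clay + C·om) / (A + 25B + 10C)` is
kept for fidelity with a published variant whose numerator adds the
scaled base threshold to raw soil percentages; the standard form is the
default because the literal numerator mixes units. Band assignment is
conservative: a concentration exactly at a threshold falls in the higher
band. Band percentages are computed in exact rational arithmetic
(`fractions.Fraction`) so they always sum to 100 before rounding.

Ecological risk uses `Er = Tr · Cn / GB` with left-closed categories
(< 40 low, 40–80 medium, 80–160 significant, 160–320 high, > 320 very
high) and shipped toxicity coefficients Tr(As) = 10, Tr(Pb) = 5,
Tr(Sb) = 7. Background values GB are site-specific config inputs, not
defaults. Descriptive statistics use the n−1 sample SD, and
CV% = 100·SD/mean; censored cells enter at their substitute value, which
keeps the statistics consistent with what PMF sees.

## Compositional data analysis

Zeros are replaced multiplicatively at 0.65·MDL before closure (simple
replacement, the common CoDA practice); compositions are closed to 1e6
(mg/kg interpretation) and clr-transformed,
`clr(x)_j = ln(x_j / g(x))`. The biplot is the SVD of the column-centred
clr matrix; the covariance form (default) scales rays so that each
element's squared ray length equals its clr variance, making ray length
proportional to clr standard deviation; the form biplot is available.
Because clr rows sum to zero the matrix is rank-deficient by one;
numerically null axes (singular value ≤ 1e-12 of the largest) are
dropped, since their directions are arbitrary. k-means clustering
operates on the full clr coordinates by default (k = 3 default, any k
configurable); clustering on two biplot axes is available for figure
parity, but the full-space default avoids discarding the variance beyond
two axes.

## Association networks and expected influence

Pairwise association defaults to Spearman rank correlation — robust to
the heavy-tailed marginals — with edges retained at
Benjamini–Hochberg-adjusted p < 0.05; Pearson and graphical-lasso
regularised partial correlations are options (the latter retained by
absolute-weight threshold since no p-values exist). Expected influence
is the one-step signed sum `EI(j) = Σ_k w_jk`; the signed default is
deliberate — an element whose associations are predominantly negative
(e.g. an atmospheric tracer anticorrelated with the geogenic block)
should carry negative EI, which an absolute-weight sum cannot express.
The absolute variant (strength centrality) and z-score standardisation
across nodes are exposed as options.

## Receptor models

**PCA.** Columns are z-scored, so components are eigenvectors of the
correlation matrix; Kaiser retention (eigenvalue > 1) applies under
`n_components="auto"`, with a warning when any eigenvalue lies within
0.05 of the cutoff (retention is then unstable, as on null data).
Varimax rotation uses Kaiser row-normalisation (rows scaled to unit
communality before rotation and rescaled after); the rotation is
orthogonal, so per-element communalities are invariant — asserted in
tests at 1e-8. Scores use the regression method `S = Z R⁻¹ L`.

**PMF.** The uncertainty matrix follows the EPA convention:
`μ_ij = sqrt((σ_j·x_ij)² + (0.5·MDL_j)²)` for detected values and
`μ_ij = (5/6)·MDL_j` at or below the MDL. The published trigger "if
MDL ≤ μ_ij" is circular (it references the quantity being defined); the
default dialect triggers on concentration ≤ MDL, with a literal dialect
retained that applies the printed condition verbatim.

The optimiser alternates exact weighted non-negative least squares over
the rows of G and the columns of F (each subproblem solved by
`scipy.optimize.nnls` on the uncertainty-scaled design). Because each
block solve is exact, the objective Q is non-increasing at every
iteration — a property asserted, not assumed, in the tests. Convergence
is declared at relative ΔQ < 1e-8 (max 2000 iterations; non-convergence
warns and returns the best iterate). Random restarts (default 20) draw
initial G, F from seeded uniform generators with child seeds spawned
from the user seed; the lowest-Q solution is kept. Factors are ordered
by explained variance, defined as
`100 · Σ_ij (g_ik f_kj)² / Σ_ij (Σ_k g_ik f_kj)²` — a weight-dominated
metric (high-concentration elements such as Fe dominate it), which is
why profile percentages, not explained variance, should be read for
source interpretation. Factor-count selection is deliberately manual; a
Q-versus-k scan helper is provided but makes no automatic choice.
Diagnostics per element: share of uncertainty-scaled residuals within
[−3, 3], signal-to-noise `sqrt(Σ max(x−μ, 0)² / Σ μ²)`, and the squared
Pearson correlation between observed and reconstructed values.

Recovered factors are matched to ground truth by optimal assignment
(Hungarian algorithm) on cosine similarity before any recovery
assertion, which resolves the permutation ambiguity; scale ambiguity is
irrelevant to cosine similarity. Note that non-negative factorisations
are only unique when the data contain near-pure rows/columns; the
recovery benchmarks are constructed accordingly (marker elements per
source, pure samples in the noiseless fixtures).

## Health risk

The deterministic engine implements the screening-level equations for
three routes. Ingestion and dermal HQs carry the 1e-6 mg→kg conversion;
inhalation divides by `RfC · PEF`, the particulate emission factor
(m³/kg) converting soil concentration to an air concentration.
Carcinogenic risks use the age-adjusted intake factors

    IFS = EF·EDa·IRSa/BWa + EF·EDc·IRSc/BWc
    DFS = EF·EDa·SAa·AFa/BWa + EF·EDc·SAc·AFc/BWc

and the inhalation route multiplies by 1000 µg/mg because the inhalation
unit risk is per µg/m³. All unit conversions live in this one module.
HI and TCR are exact route sums; every risk is linear in concentration —
the property the Monte Carlo and source-apportionment layers exploit.

Routes whose toxicity input is absent are reported as `None` and listed
in `missing_routes`, never silently zeroed, so a small HI computed
without an inhalation reference concentration is auditable. Risk bands:
HI ≥ 1 unacceptable; CR < 1e-6 ignorable, [1e-6, 1e-4] notable
(boundaries inclusive on the notable side), > 1e-4 unacceptable.

Shipped exposure defaults follow the USEPA RSL resident scenario (child:
IRS 200 mg/d, ED 6 y, BW 15 kg, SA 2373 cm², AF 0.2; adult: 100 mg/d,
20 y, 80 kg, 6032 cm², 0.07; EF 350 d/y; PEF 1.36e9 m³/kg;
carcinogenic AT 70·365 d), and the toxicity table carries RSL-style
values for As, Pb, Sb, Cd, Cr, Ni (e.g. As: RfDo 3e-4 mg/kg-d, CSFo 1.5
(mg/kg-d)⁻¹, IUR 4.3e-3 (µg/m³)⁻¹, RBA 0.6, ABSd 0.03). These are
screening defaults; site assessments should override them via the YAML
config loaders.

## Monte Carlo risk

Only concentrations are stochastic by default; exposure parameters stay
deterministic (their distributions are site-specific and rarely
published). The default concentration family is lognormal fitted by
moment matching — exact in closed form, preserving the observed mean and
SD — with log-scale maximum likelihood and empirical bootstrap as
alternatives; a constant vector yields a degenerate point mass in any
family. Each iteration draws one concentration per element, evaluates
the deterministic equations and accumulates per-element and total HI/TCR
draws (default 1000 iterations, reported at the mean and the 95th
percentile, linear-interpolation percentile estimator). Exceedance
probabilities are reported for HI > 1 and the CR band boundaries. The
distribution mean uses `math.fsum` (correctly rounded summation), so the
degenerate zero-variance limit reproduces the deterministic result
exactly rather than to within accumulation error. Contribution shares
are same-draw: `100 · mean(element risk) / mean(total risk)`, summing to
100 exactly.

## Source-oriented risk

Each PMF factor's apportioned concentration table is
`C(k)_ij = g_ik · f_kj`, summing to the reconstruction GF exactly. Risk
is computed from per-sample apportioned concentrations, not from mean
profile × mean contribution, preserving the between-sample variability
the Monte Carlo needs. In deterministic mode, linearity makes per-factor
risks sum exactly to the risk of GF. In Monte Carlo mode each factor's
concentrations are refitted and simulated with the same machinery as the
total-risk pipeline (factor cells of exactly zero get a point mass at
zero; columns containing zeros fall back to bootstrap, since a lognormal
cannot be fitted); factors receive decorrelated child seeds spawned from
the config seed, so restricting the factor subset never shifts other
factors' draws. The per-factor no-risk probability is the share of draws
with HI ≤ 1.

## Orchestration and reproducibility

The pipeline expands one global seed into per-stage child seeds via
`numpy.random.SeedSequence(seed, spawn_key=(stage_index,))` with a fixed
stage numbering, so toggling stages never shifts another stage's random
stream; reruns with the same config are byte-identical. Problem sizes
used by the test suite and the acceptance script — 30-sample default
survey, a 200-sample 3-source recovery benchmark at 10% noise with 20
PMF restarts, 1e4 Monte Carlo iterations for tail checks, 1e6 draws for
moment-matching checks — were chosen as the smallest sizes at which the
respective statistical tolerances are comfortably resolvable.

## Known limitations

* PMF provides no rotational-ambiguity or bootstrap uncertainty on G and
  F (no DISP/BS analogues); attribution uncertainty in source-oriented
  risk is correspondingly unquantified.
* Monte Carlo sampling is per-element independent; correlated
  multivariate concentration sampling is future work.
* The shipped exposure/toxicity numbers are screening-level defaults,
  not a substitute for a site-specific, endpoint-reviewed table.
* The generator produces no spatial structure, so map-based
  interpretation stages have no synthetic counterpart.
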