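# Methods

`friedel` is a desk-scale re-implementation of the computational core of an
automated experimental-phasing pipeline for macromolecular crystallography:
from anomalous/isomorphous difference data to substructure detection,
likelihood-based phasing with Hendrickson–Lattman (HL) statistics, density
modification with correlation-aware phase combination and cross-validated
error estimation, and hand determination.  A synthetic-crystal simulator
provides ground truth for every stage, standing in for large real data-set
benchmarks.  This note records the models, the numerical choices, and what
the synthetic tests do and do not demonstrate.

## The synthetic crystal

The simulator builds a toy crystal: `n_light` carbon-like point scatterers
(f″ = 0) placed uniformly in an asymmetric unit with pairwise separation
≥ 1.5 Å, plus a few anomalous scatterers (separation ≥ 3 Å) with
user-specified f′ and f″.  Scattering uses a single-Gaussian form factor
f0(s) = Z·exp(−w·s²) with s = 1/d and a small per-element width table
(C: w = 3.0 Å², Se: 1.6 Å², Hg: 1.2 Å², …) — this keeps the resolution
falloff of real form factors without shipping Cromer–Mann tables.
Debye–Waller damping is exp(−B·s²/4) with light-atom B uniform in
[10, 30] Å² and heavy B in [15, 25] Å².  Structure factors are exact direct
summations over sites and symmetry operators (no FFT approximation); the
phase argument is wrapped modulo one lattice period before the complex
exponential so Friedel's law at f″ = 0 holds to strict machine precision.

Measurement noise is independent Gaussian on each Friedel mate's amplitude
with σ = noise_frac·⟨|F|⟩ per resolution shell; centric reflections (and
native sets) receive one shared draw because they are one measurement.
`noise_frac = 0` reproduces the noise-free amplitudes bit-exactly.  Real
data features deliberately *not* modelled: bulk-solvent contribution,
anisotropic displacement, correlated Friedel-pair integration errors,
unmerged multiplicity, radiation damage.  Consequently a passing test here
shows the algorithms are correct and well-calibrated under clean
assumptions, not that they survive every pathology of real data.

The reference problem used throughout ("toy50") is a P2₁ crystal,
34 × 42 × 38 Å, 150 light atoms, two Se sites with f′ = −2, f″ = 4
(f′ is our choice; only f″ is pinned by the study conditions), d_min
2.2 Å, 5% amplitude noise — about 5 600 unique reflections with an overall
Bijvoet ratio near 0.10.

Space-group support is deliberately minimal — P1, P2₁, P2₁2₁2₁ with
hard-coded, closure-tested operator tables — enough for acentric phasing,
Harker sections, centric zones, and origin/hand ambiguities.  Centric phase
restrictions are derived from the operator that negates the index:
φ ≡ 180°·(h·t) mod 180°, which correctly yields ±90° restrictions for
odd-parity zones of P2₁2₁2₁ (not only 0/180°).

## Multivariate |F_A| estimation

The classical heavy-atom amplitude estimate is |ΔF| = ||F⁺| − |F⁻||.  The
multivariate estimator instead returns the posterior expectation
E[|F_A| given |F⁺|, |F⁻|, σ⁺, σ⁻] under a generative model: heavy and
protein components complex Gaussian per shell (heavy fraction a parameter,
default 0.05), uniform relative phase θ between the heavy and total
structure factors, noisy amplitudes.  Conditioning on θ makes the Bijvoet
difference linear in the heavy amplitude a, so every amplitude integral
∫ aᵏ·exp(−a²/Σ_A)·N(ΔF; c(θ)·a, σ_d²) da is a truncated-Gaussian moment in
closed form, and a single 64-point Gauss–Legendre quadrature over θ remains.
The anomalous coupling c is set per shell by matching ⟨ΔF²⟩.  The estimator
is validated against a dense 3-D quadrature of the *unreduced* model (exact
mate amplitudes, Rice observation terms, heavy amplitude × protein
amplitude × relative phase) to 2% RMS; in the no-information limit it
returns the Rayleigh prior mean, and it is monotone in |ΔF|.  Because it
shrinks noise-dominated differences toward the prior mean, it correlates
substantially better with the true heavy amplitudes than |ΔF| does
(≈ 0.63 vs ≈ 0.47 on the reference problem at 5% noise).

## Substructure search

A sharpened anomalous-difference Patterson map P(u) = Σ (E² − ⟨E²⟩)
cos(2π h·u), expanded over the Patterson symmetry, drives a deterministic
multi-trial search: random translation candidates scored by the
symmetry-minimum function locate site 1 on the Harker section(s) (for P2₁
the free coordinate along the screw axis is fixed at zero — the origin is
polar there); subsequent sites come from Patterson-peak translations of all
symmetry images of the known sites, scored by the minimum cross-vector
value; occupancies are fit by least squares on the normalized |F_A|; each
trial ends with a Nelder–Mead polish of coordinates and relative
occupancies against the trial score, the Pearson correlation between
normalized observed and calculated heavy amplitudes.  Grid spacing is
d_min/3 with three-point parabolic peak interpolation.  On the reference
problem the search places both sites within ≈ 0.1 Å.

Early termination follows two rules: stop when the best trial score
reaches a threshold (default 0.65), or when at least five trials are done,
the best–worst spread exceeds 0.2 and the best score is at least 0.4.  The
thresholds are package choices; at 5% noise on the toy problem correct
solutions score ≈ 0.35 (the score is capped by noise in the |F_A|
estimates), so in practice the likelihood-based completeness check below is
the operative validator, matching the pipeline design.

Found solutions are matched to ground truth by exhaustive search over
hand × symmetry operator × allowed origin shifts (continuous components
solved from an anchor pair, discrete ones snapped to the allowed values),
with greedy bipartite assignment on cell-metric distances.

## Joint-Friedel likelihood phasing

For each protein phase φ on a 72-point grid the model structure factors
are F±(φ) = x·e^{iφ} + d·β·F_H(±h), with x the (unknown) protein
amplitude, F_H the substructure transform, d the per-shell Luzzati
parameter, and β a per-shell power rescale described below.  The
likelihood is the product of two Rice terms in |F⁺| and |F⁻| — the two
mates are treated jointly, never merged into a single ΔF with a pooled σ.
The protein amplitude is a nuisance: its conditional mode per
(reflection, φ) is found by four Gauss–Newton steps (with a Rayleigh prior
from the shell's Wilson statistics), and it is then marginalized with a
7-point Gauss–Hermite quadrature about the mode.  The amplitude fold
|x·e^{iφ} + F_H| can admit a second positive mode; a mirrored second
Newton start catches it and the two local quadratures are combined through
a smooth separation gate (a hard gate would make the likelihood
discontinuous in the model parameters).  Centric reflections get the real
(signed) protein amplitude marginalized on a 96-point grid over a Wilson
prior; the sign selects between the two allowed phases.

One subtle point is worth recording: the Rice density's normalization is
x/σ² — a *full* −log σ² per mate, not the Gaussian −½·log σ².  Using the
Gaussian form reverses model-comparison orderings entirely (inflated
variances become nearly free), and every error-parameter refinement
collapses to d = 0.

A merged-difference Gaussian reference mode — one Gaussian on
ΔF with σ_ΔF = (σ⁺² + σ⁻²)^½, the classical treatment — is implemented for
comparison; the joint treatment matches or beats it on the mean cosine
phase error across the reference seeds.

### Luzzati error parameters and the completeness check

The per-shell Luzzati parameter d must behave like a model-quality
correlation: d → 1 for a complete correct substructure, ≈ √½ for half of
it, → 0 for an unrelated one.  A free regression coefficient on the raw
F_H would not do this (a correct-but-incomplete model still gets
coefficient 1, with the missing sites absorbed as extra variance).  Two
ingredients make d identifiable: (1) the model heavy transform is rescaled
per shell by β = the solution of the moment relation
⟨ΔF² − σ_d²⟩ = β²·q·(Σ_T − β²·Σ_M)/Σ_T, where q is the model's
anomalous-difference power ⟨|F_H(h) − F_H(−h)*|²⟩/2 (a composition
property, independent of whether the site positions are right) and the
Σ_P/Σ_T factor accounts for the attenuation of the anomalous lever arm by
the heavy fraction of the total structure factor; (2) the unmodelled
anomalous signal appears as variance 0.25·(1 − d²)·Σ_A per mate, with
Σ_A the observed Bijvoet excess — the part of the signal the
protein-amplitude nuisance cannot absorb.  A free non-negative var_extra
per shell absorbs residual miscalibration.  (d, var_extra) are refined
per shell by Nelder–Mead on the marginal likelihood with a multi-start
(the landscape can have basins at low and high d), on a deterministic
subsample of at most 120 reflections per shell.

The quick completeness check refines this error model with a reduced
iteration budget and declares the substructure complete when the
reflection-weighted average d exceeds 0.7.  On the reference problem the
full correct substructure averages ≈ 0.85, half of it ≈ 0.55, random
sites ≈ 0.3–0.45.

### Site refinement

Sites are refined cyclically (coordinates by Nelder–Mead, occupancy/B by
bounded quasi-Newton, occ ∈ (0, 2], B ∈ [2, 100] Å²) against the marginal
likelihood under a *fixed reference* error model (d capped at 0.9, a small
variance floor replacing var_extra): letting the error parameters float
would let them absorb exactly the model errors the refinement must see.
The objective uses a stride subsample — ranking reflections by amplitude
would discard the weak ones, which carry most of the anomalous leverage.
Two honest limitations: the absolute occupancy scale is unidentifiable
(the β rescale absorbs it; only occupancy ratios are refined meaningfully),
and the refinement radius is modest — a 0.4 Å perturbation at zero noise
is reduced to ≈ 0.2 Å, not to hundredths of an Ångström, because the
profile-marginal surface has a flat diagonal valley.  In the pipeline this
is immaterial: the Patterson search already delivers ≈ 0.1 Å accuracy and
refinement never degrades its own objective.

### SIRAS

The uncorrelated SIRAS posterior replaces the protein-amplitude proxy by
the per-shell-scaled native amplitude and adds the native measurement
variance to both Rice terms, treating the two error channels as
independent.  When the native set carries no isomorphous information it
reduces to the SAD posterior exactly.  Derivative/native scaling is plain
per-shell least squares — accurate for realistic (small) heavy fractions,
biased when the substructure dominates the scattering, which is a known
limit of moment-based scaling.

### HL coefficients and figures of merit

Posteriors are summarized as HL coefficients by probability-weighted least
squares of the log-posterior on {1, cos φ, sin φ, cos 2φ, sin 2φ}; the
centroid phase and figure of merit come directly from the grid.  The
fom implied by the fitted coefficients reproduces the grid fom within 0.02
across random HL-shaped posteriors.  Centric reflections carry two-point
distributions encoded as (A, B) along the allowed phase axis.

## Density modification

One cycle is: fom-weighted Fourier synthesis (free reflections get zero
weight so the cross-validation below stays honest) → solvent mask (local
mean of |ρ| over a sphere, lowest-quantile, symmetry-averaged) → flatten
(or flip) the solvent → back-transform at the observed reflections →
estimate combination error parameters → combine with the experimental
phase distribution.  The synthesis/back-transform round trip is exact to
machine precision for band-limited maps at or above Nyquist sampling.

The solvent-averaging radius defaults to 1.0·d_min.  Classical solvent
flattening uses larger radii (≈ 2.5·d_min), but those over-smooth
discrete-atom toy structures — measured on the reference problem, the
large radius makes the modified map's phases *worse* than the input
(mean cos error 0.55 vs 0.72), while 1.0·d_min improves them.  The solvent
fraction defaults to 0.45; point-atom toys have much larger truly-empty
fractions, so this is conservative (flattening only clearly-solvent
regions).  Flip factor 1.0; flattening is the default mode.

### Phase combination and cross-validated calibration

The density-modified (DM) phase channel enters as a von Mises term with
concentration κ = 2·d_dm·E_obs·E_dm/(1 − d_dm²) on normalized amplitudes —
exactly HL-form, so combination adds (κ·cos φ_dm, κ·sin φ_dm) to (A, B).
Two modes:

* **mlhl** — the classical product, assuming the experimental and DM
  channels independent, with d_dm fitted on all reflections.
* **multivariate** — the DM information is discounted by a per-shell
  redundancy fraction α: κ_eff = (1 − α)·κ.  α = 1 makes the DM channel
  fully redundant (output = experimental posterior, exactly); α = 0
  recovers the MLHL product, exactly.

The cross-validated scheme fits d_dm twice per shell: on the free
reflections only — whose experimental phases never entered any map, so
this is the honest information content — and on the work reflections,
where feedback inflates the apparent map quality.  α is the measured
information excess, α = 1 − κ(d_free)/κ(d_work), so that work reflections
receive exactly the free-calibrated information.  Shells with fewer than
30 usable reflections fall back to a pooled fit (a thin shell can chase
noise; with a 5% free fraction the free shells are always thin, so the
free-set fit is effectively global).  The effect on the reference problem:
combined figures of merit track the true cos(phase error) within ≈ 0.05,
while the naive MLHL product escalates them by ≈ 0.2–0.3.

### Hand determination

Both substructure hands are phased and density-modified identically; the
decision statistic is the predictive log-likelihood of the DM phases on
the free reflections under the CV-calibrated channel.  A difference below
1.0 per 100 free reflections is declared undetermined — a centrosymmetric
substructure (e.g. one site at the origin in P1) lands there by
construction.  On the reference problem the correct hand wins by tens of
log-units.

## Pipeline

The orchestrator runs fa → detect → phase → dm → hand with
experiment-dependent defaults: SAD uses the multivariate |F_A| estimate
and multivariate (CV-calibrated) combination; SIRAS chooses between
anomalous and isomorphous signal by the greater per-shell signal score,
phases with the uncorrelated SIRAS function and combines with MLHL; MAD
selects the channel with the greatest anomalous signal and then follows
the SAD path with MLHL combination.  All randomness derives from one root
seed via step-name-hashed offsets; reports are byte-reproducible.  On
synthetic runs the detected substructure is placed in the simulator's
truth frame (hand, symmetry operator and allowed origin shift are exact
symmetries of the amplitude data) so that truth metrics in the report are
interpretable.

## Problem sizes and budgets

Defaults were chosen so a full toy50 pipeline runs in about a minute and
the whole test suite in well under half an hour: 72-point phase grids
(24-point internally during site refinement), 10 resolution shells,
at most 120 reflections per shell during error-model refinement, three
search trials per seed in batch evaluations (the Patterson search is
deterministic given the map, so additional trials reproduce the same
solution), five density-modification cycles, and 20 (or 10) simulation
seeds in the multi-seed checks, matching the stated study conditions.

## Known limitations

* Amplitude-level input only; no intensity-to-amplitude conversion,
  scaling/merging, or full space-group library.
* The multivariate |F_A| reduction drops the information in the Friedel
  *mean* and linearizes the Bijvoet difference; both are excellent
  approximations at small heavy fractions but degrade for reflections with
  near-zero protein amplitude.
* Site refinement recovers occupancy ratios, not absolute occupancies,
  and has a ≈ 0.2 Å accuracy floor (see above).
* Derivative/native scaling is biased when the substructure dominates.
* No multi-wavelength joint MAD likelihood and no correlated
  (multivariate) SIRAS function; MAD is handled by best-channel selection.
* No NCS handling, histogram matching, or model building.
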