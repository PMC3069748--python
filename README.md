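# friedel

Desk-scale experimental phasing for macromolecular crystallography: from
anomalous (SAD/MAD) or isomorphous-plus-anomalous (SIRAS) difference data
to heavy-atom substructure detection, likelihood-based phasing, density
modification with cross-validated phase combination, and hand
determination — with a synthetic-crystal simulator that deposits ground
truth (true phases, true heavy-atom structure factors, site lists) for
every stage.

It is aimed at people who want to study, teach, or prototype the
*algorithms* of experimental phasing on problems that run in seconds to
minutes, with every intermediate quantity checkable against simulator
truth — not at people solving real deposited datasets.

## The methods in brief

* **|F_A| estimation.** Besides the classical |ΔF| = ||F⁺| − |F⁻||, a
  multivariate estimator returns E[|F_A| | |F⁺|, |F⁻|, σ⁺, σ⁻] under
  complex-Gaussian priors, reduced to a *single* numerical integration
  over the heavy-vs-total relative phase (all amplitude integrals are
  closed-form truncated-Gaussian moments).  It is tested against a dense
  3-D quadrature oracle.
* **Substructure search.** Sharpened anomalous-difference Patterson map;
  symmetry-minimum function on the Harker sections for the first site,
  cross-vector-consistent peak translations for the rest; multi-trial with
  early-termination rules (score threshold, best–worst deviation).
* **Phasing.** For each protein phase φ, model F±(φ) = x·e^{iφ} + d·β·F_H(±h)
  with the protein amplitude x marginalized numerically and *both* Friedel
  mates entering as separate Rice likelihood terms — the measurement errors
  are never merged into one σ(ΔF).  Output is per-reflection
  Hendrickson–Lattman coefficients (A, B, C, D), centroid phase and figure
  of merit m = |⟨e^{iφ}⟩|.  Per-shell Luzzati parameters d are refined by
  maximum marginal likelihood and power the "check mode": a substructure is
  judged complete when the average d exceeds 0.7.
* **Density modification.** Solvent flattening (or flipping) iterated with
  likelihood phase combination.  The density-modified phase channel enters
  as a von Mises term κ·cos(φ − φ_DM); in the multivariate mode the
  redundant-information fraction α per shell — measured by comparing fits
  on cross-validation (free) reflections against work reflections —
  discounts it to (1 − α)·κ, which keeps figures of merit honest instead
  of escalated.
* **Hand determination.** Both enantiomorphic substructures are carried
  through density modification; the cross-validated free-set likelihood of
  the DM phases picks the hand (or declares it undetermined).

See `docs/methods.md` for the full model descriptions, parameter defaults
and known limitations.

## Worked example

```python
from friedel import SADPhasingModel, flag_free_set, simulate_toy50
from friedel.density import run_dm_cycles, determine_hand

# a P21 toy crystal: 150 light atoms + 2 Se sites, d_min 2.2 A, 5% noise
structure, data, truth = simulate_toy50(seed=0)
data = flag_free_set(data, 0.05, seed=101)

model = SADPhasingModel(data, structure.heavy)
res = model.fit()
print(res.summary(truth))

dm = run_dm_cycles(data, res.phases, res.error_model, n_cycles=5,
                   mode="multivariate", truth=truth)
print(dm.summary())

hand, stats = determine_hand(data, res.substructure, res.error_model)
print("hand:", hand)
```

The summary starts like this (trimmed):

```
SAD substructure phasing results
================================================
reflections: 5561   sites: 2   mode: joint
avg Luzzati d: 0.8434   mean FOM: 0.6086
...
vs truth: mean cos(dphi) = 0.7267, fom-weighted |dphi| = 24.1 deg, map CC = 0.7808
cycle  mean_fom   free_ll   mean_cos_err
    1    0.8122      39.3        0.7868
    ...
    5    0.8807      48.2        0.8138
hand: original
```

An average Luzzati parameter of 0.84 (> 0.7) is what the pipeline's check
mode reads as "the substructure is complete"; the figure of merit ≈ 0.61
says the phase distributions are informative; the mean cosine of the phase
error vs the simulator truth (0.73) and the map correlation (0.78) measure
actual phase quality, available only because the data are synthetic.  The
density-modification log shows the mean cosine error climbing from 0.73 to
0.81 over five cycles, and the hand decision comes back `original` with a
free-set log-likelihood margin of tens of units.

The same run, driven end to end from the shell:

```bash
friedel run --config examples/toy_sad.yaml --seed 1 --out out/
friedel report out/report.json
```

(the repository ships `examples/toy_sad.yaml` with exactly the reference
toy problem; steps, per-step parameters, input files and the heavy-atom
specification are all configurable there).

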