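# rrsemen

Random-regression (RR) animal-model analysis of longitudinal boar semen
traits: quality control of repeated ejaculate records, pedigree
relationship matrices, Legendre-basis covariance functions, REML
variance-component estimation, BIC polynomial-order selection, and
age-trajectory genetic parameters — with a synthetic-data generator so
every stage is testable against known truth.

**Who it is for.** Animal-breeding researchers and students analyzing
repeated sex-limited records (semen volume, motility, concentration,
abnormal-sperm percentage collected over a boar's working life at AI
centers) who need age-specific heritabilities, repeatabilities and
between-age genetic correlations rather than a single repeatability-model
estimate.

## Model

For a record of boar *k* at age *t* (weeks) in AI-center×year×month
class *i* and collection-interval class *j*:

```
y_ijkt = AIYS_i + Interval_j + Σ_l φ_l(w_t)β_l + Σ_l φ_l(w_t)a_kl + Σ_l φ_l(w_t)pe_kl + e_ijkt
```

with standardized age `w_t = −1 + 2(t − a_min)/(a_max − a_min)` and the
normalized Legendre basis `φ_l(w) = sqrt((2l+1)/2)·P_l(w)`. In matrix
form `y = X1 b1 + X2 b2 + Z1 a + Z2 p + e` with `var(a) = K_a ⊗ A`
(A = pedigree numerator relationship matrix), `var(p) = K_p ⊗ I`,
`var(e) = I σ_e²`. Candidate models `L(a,b,c)` differ in the polynomial
degrees of the fixed, additive-genetic and permanent-environment
regressions and are ranked by `BIC = −2 log L + P log n`. Age
trajectories follow from the fitted coefficient covariances:
`σ_a²(t) = φ(t)'K_a φ(t)`, `h²(t) = σ_a²/(σ_a²+σ_pe²+σ_e²)`,
`r(t₁,t₂) = φ(t₁)'K_aφ(t₂)/√(σ_a²(t₁)σ_a²(t₂))`.

See `docs/methods.md` for assumptions, estimation details and the
design of the validation experiments.

## Worked example

Simulate a population with known truth, run QC, fit the generating
model and report trajectories (about 15 s):

```python
import rrsemen as rr
from rrsemen.simulate import SimConfig, simulate_dataset

cfg = SimConfig(seed=1, n_founder_sires=25, n_founder_dams=80,
                n_gen1_males=125, n_gen1_females=50, n_gen2_males=125,
                records_per_boar=(12, 22))
records, ped, truth = simulate_dataset(cfg)
filtered, report = rr.apply_qc(records, rr.QCConfig(), trait="vol")
print(report.to_text())

design = rr.build_design(filtered, rr.ModelSpec("vol", 2, 1, 2), ped,
                         cfg.standardizer())
fit = rr.fit_reml(design, rr.build_nrm_inverse(ped),
                  opts=rr.REMLOptions(tol=1e-5))
print(f"logL = {fit.loglik:.1f}   BIC = {fit.bic:.1f}   converged = {fit.converged}")

traj = rr.variance_trajectory(fit.varcomp, ages=[40, 70, 100, 130],
                              s=cfg.standardizer())
print(traj.to_frame().round(3).to_string(index=False))
```

Output:

```
input records: 4233
removed by trait_range_vol: 187
removed by age_window: 0
removed by first_record_or_interval: 230
removed by min_ejaculates_per_boar: 5
removed by fixed_level_count_aiys: 81
removed by fixed_level_count_interval_class: 11
surviving records: 3719
surviving boars: 247
fixed-point passes: 3
logL = -20219.3   BIC = 40463.2   converged = True
 age_weeks  sigma_a2  sigma_pe2  sigma_e2    h2  repeatability
      40.0  1310.113    339.320   3550.24 0.252          0.317
      70.0   886.283    320.634   3550.24 0.186          0.254
     100.0   845.422    818.567   3550.24 0.162          0.319
     130.0  1187.529   1561.212   3550.24 0.189          0.436
```

Reading it: the QC report attributes each removed row to the first
criterion that caught it (here mostly first-record/interval removals and
thin AI-center×month classes). The fitted additive variance `sigma_a2`
and permanent-environment variance `sigma_pe2` are age-specific
quadratic forms of the estimated coefficient covariances; with the
generating values (σ_a² between roughly 680 and 1370, σ_e² = 4000) this
247-boar run recovers heritabilities around 0.15–0.25 across ages, as
expected for semen volume.

The same pipeline runs from the shell:

```sh
rrsemen simulate --config sim.yaml --out data/
rrsemen run --config analysis.yaml --out results/   # QC → fit/grid → reports
```

Every artifact directory gets a `MANIFEST.json` of content hashes;
reruns with the same config and seed are byte-identical.

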