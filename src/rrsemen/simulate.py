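"""Synthetic pedigrees and longitudinal semen-trait records with known truth.

The generator emulates the structure of AI-center boar studbook data:
a three-generation pedigree, repeated ejaculate records per boar over
ages 33-150 weeks at 1-30 day collection intervals, AI-center x year x
month (AIYS) fixed effects, collection-interval effects, a fixed
Legendre mean curve, and additive-genetic / permanent-environment
random-regression coefficients drawn from known covariance matrices
with homogeneous residual noise.

Default truth values are on the scale of semen volume (ml): a mean
curve rising from ~240 ml to a plateau around 80 weeks, additive
variance ~680-1370, permanent-environment variance ~680-1430, residual
4000 - giving heritability ~0.11-0.22 and repeatability ~0.3-0.5 over
the age range. Every draw is driven by a mandatory seed and fully
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .legendre import AgeStandardizer, basis_matrix
from .pedigree import Pedigree, mendelian_variance, sort_pedigree

__all__ = ["SimConfig", "simulate_pedigree", "simulate_coefficients",
           "simulate_records", "simulate_dataset", "write_records",
           "write_pedigree"]


def _default_interval_effects() -> np.ndarray:
    # rises over 1-9 day intervals, then declines (volume-like response)
    up = np.linspace(0.0, 20.0, 9)
    down = 20.0 - 0.75 * np.arange(1, 22)
    return np.concatenate([up, down])[:30]


@dataclass
class SimConfig:
    """Generator configuration; the defaults are the study conditions."""

    # pedigree structure (three generations)
    n_founder_sires: int = 20
    n_founder_dams: int = 150
    n_gen1_males: int = 250
    n_gen1_females: int = 150
    n_gen2_males: int = 250
    n_gen2_females: int = 0
    n_gen3_males: int = 0
    founder_sires_recorded: bool = False
    males_per_litter: tuple = (1, 1)   # full brothers retained per mating

    # record structure
    age_min: float = 33.0
    age_max: float = 150.0
    entry_age_weeks: tuple = (33, 115)      # uniform window of first collection
    records_per_boar: tuple = (12, 28)      # uniform; collection stops at age_max
    interval_mode_days: int = 5             # mode of the 1-30 day interval law
    interval_max_days: int = 30

    # fixed effects
    n_centers: int = 3
    aiys_sd: float = 30.0
    start_date: str = "2015-01-01"
    interval_effects: np.ndarray = field(default_factory=_default_interval_effects)

    # truth (semen-volume scale, ml)
    trait: str = "vol"
    beta: np.ndarray = field(default_factory=lambda: np.array([350.0, 25.0, -10.0]))
    k_a: np.ndarray = field(default_factory=lambda: np.array(
        [[1600.0, 200.0], [200.0, 150.0]]))
    k_p: np.ndarray = field(default_factory=lambda: np.diag(
        [1200.0, 350.0, 120.0]))
    sigma_e2: float = 4000.0

    seed: int = 0

    def standardizer(self) -> AgeStandardizer:
        return AgeStandardizer(self.age_min, self.age_max)

    def truth_dict(self) -> dict:
        d = asdict(self)
        for k in ("beta", "k_a", "k_p", "interval_effects"):
            d[k] = np.asarray(d[k]).tolist()
        return d


def _interval_sampler(cfg: SimConfig, rng: np.random.Generator):
    """Discrete interval law on 1..30 days with mode near cfg.interval_mode_days.

    A shifted negative binomial truncated at the maximum: right-skewed,
    mode at the configured value, like an AI-center collection schedule
    with occasional long pauses.
    """
    mode = cfg.interval_mode_days
    r = 4.0
    p = r / (r + max(mode - 1, 0.5))  # NB mode = floor((r-1)(1-p)/p)
    support = np.arange(0, cfg.interval_max_days)  # shifted by +1 below
    from scipy import stats

    pmf = stats.nbinom.pmf(support, r, p)
    pmf = pmf / pmf.sum()

    def draw(size: int) -> np.ndarray:
        return 1 + rng.choice(support, size=size, p=pmf)

    return draw


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Random-mating three-generation pedigree.

    Returns (Pedigree, record_boars): record_boars are the generation-1
    and generation-2 males, so parent-offspring pairs both carry
    records (as in a studbook spanning several cohorts).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    triples = []
    sires = [f"S{i:04d}" for i in range(cfg.n_founder_sires)]
    dams = [f"D{i:04d}" for i in range(cfg.n_founder_dams)]
    for a in sires + dams:
        triples.append((a, None, None))

    females = list(dams)
    males_prev = sires
    record_boars: list[str] = list(sires) if cfg.founder_sires_recorded else []
    lit_lo, lit_hi = cfg.males_per_litter
    per_gen = [(cfg.n_gen1_males, cfg.n_gen1_females),
               (cfg.n_gen2_males, cfg.n_gen2_females),
               (cfg.n_gen3_males, 0)]
    for gen, (n_m, n_f) in enumerate(per_gen, start=1):
        males_new = [f"M{gen}{i:04d}" for i in range(n_m)]
        females_new = [f"F{gen}{i:04d}" for i in range(n_f)]
        if males_prev and females:
            # males arrive litter-wise: full brothers share one mating
            i = 0
            while i < n_m:
                sire, dam = rng.choice(males_prev), rng.choice(females)
                for _ in range(int(rng.integers(lit_lo, lit_hi + 1))):
                    if i >= n_m:
                        break
                    triples.append((males_new[i], sire, dam))
                    i += 1
            for a in females_new:
                triples.append((a, rng.choice(males_prev), rng.choice(females)))
        else:
            for a in males_new + females_new:
                triples.append((a, None, None))
        females += females_new
        record_boars += males_new
        if males_new:
            males_prev = males_new
    ped = sort_pedigree(triples)
    return ped, record_boars


def simulate_coefficients(ped: Pedigree, k_a: np.ndarray, k_p: np.ndarray,
                          record_boars, rng: np.random.Generator):
    """Draw additive coefficient vectors down the pedigree plus PE vectors.

    Founders ~ N(0, K_a); offspring = parent average + Mendelian term
    with covariance d_i * K_a, d_i = 1 - 0.25(1+F_s) - 0.25(1+F_d) per
    known parent. PE vectors are i.i.d. N(0, K_p) per record boar.
    """
    def chol(K: np.ndarray) -> np.ndarray:
        if np.allclose(K, 0.0):
            return np.zeros_like(K)
        return np.linalg.cholesky(K + 1e-12 * np.trace(K) * np.eye(K.shape[0]))

    k_a = np.asarray(k_a, dtype=float)
    ka = k_a.shape[0]
    n = len(ped)
    La = chol(k_a)
    d = mendelian_variance(ped, with_inbreeding=True)
    a = np.zeros((n, ka))
    z = rng.standard_normal((n, ka))
    for i in range(n):
        mean = np.zeros(ka)
        if ped.sire[i] >= 0:
            mean += 0.5 * a[ped.sire[i]]
        if ped.dam[i] >= 0:
            mean += 0.5 * a[ped.dam[i]]
        a[i] = mean + np.sqrt(d[i]) * (La @ z[i])
    k_p = np.asarray(k_p, dtype=float)
    Lp = chol(k_p)
    pe = {b: Lp @ rng.standard_normal(k_p.shape[0]) for b in record_boars}
    return a, pe


def simulate_records(ped: Pedigree, a: np.ndarray, pe: dict, cfg: SimConfig,
                     rng: np.random.Generator,
                     include_first_record: bool = True) -> pd.DataFrame:
    """Generate the longitudinal record table with hidden truth columns.

    Columns ``truth_*`` carry the generating components for test
    assertions; :func:`write_records` strips them so that pipeline input
    files stay honest. With ``include_first_record=False`` each boar's
    first collection is omitted while its successor keeps the true
    interval (emulating a pre-filtered extract).
    """
    s = cfg.standardizer()
    draw_interval = _interval_sampler(cfg, rng)
    start = pd.Timestamp(cfg.start_date)
    lf = len(cfg.beta) - 1
    ka = np.asarray(cfg.k_a).shape[0]
    kp = np.asarray(cfg.k_p).shape[0]
    aiys_effects: dict[str, float] = {}
    rows = []
    record_boars = list(pe.keys())
    lo_n, hi_n = cfg.records_per_boar
    lo_e, hi_e = cfg.entry_age_weeks
    for b in record_boars:
        ai = a[ped.index[b]]
        pb = pe[b]
        center = f"C{rng.integers(cfg.n_centers)}"
        birth = start + pd.Timedelta(days=int(rng.integers(0, 730)))
        n_rec = int(rng.integers(lo_n, hi_n + 1))
        age_days = 7 * int(rng.integers(lo_e, hi_e + 1))
        intervals = draw_interval(n_rec)
        intervals[0] = 0
        for j in range(n_rec):
            age_days += int(intervals[j])
            age_weeks = age_days // 7
            if age_weeks > cfg.age_max:
                break
            date = birth + pd.Timedelta(days=age_days)
            aiys = f"{center}|{date.year}|{date.month}"
            if aiys not in aiys_effects:
                aiys_effects[aiys] = rng.normal(0.0, cfg.aiys_sd)
            phi_f = basis_matrix([age_weeks], lf, s)[0]
            phi_a = basis_matrix([age_weeks], ka - 1, s)[0]
            phi_p = basis_matrix([age_weeks], kp - 1, s)[0]
            g = float(phi_a @ ai)
            p_val = float(phi_p @ pb)
            fixed_age = float(phi_f @ np.asarray(cfg.beta))
            iv_eff = (float(cfg.interval_effects[int(intervals[j]) - 1])
                      if j > 0 else 0.0)
            resid = rng.normal(0.0, np.sqrt(cfg.sigma_e2))
            y = aiys_effects[aiys] + iv_eff + fixed_age + g + p_val + resid
            rows.append({
                "boar": b, "date": date, "center": center,
                "age_weeks": float(age_weeks),
                "interval_days": float(intervals[j]) if j > 0 else np.nan,
                "aiys": aiys,
                "interval_class": int(intervals[j]) if j > 0 else pd.NA,
                cfg.trait: y,
                "truth_g": g, "truth_pe": p_val, "truth_fixed_age": fixed_age,
                "truth_aiys": aiys_effects[aiys], "truth_interval": iv_eff,
                "truth_resid": resid, "first_record": j == 0,
            })
    df = pd.DataFrame(rows)
    if len(df) == 0:
        raise ValueError("no records generated: age window too small")
    if not include_first_record:
        df = df[~df["first_record"]].reset_index(drop=True)
    df["interval_days"] = pd.array(df["interval_days"], dtype="Float64")
    df["interval_class"] = pd.array(df["interval_class"], dtype="Int64")
    df.attrs["aiys_effects"] = aiys_effects
    return df


def simulate_dataset(cfg: SimConfig, include_first_record: bool = True):
    """Full generation pass: pedigree, coefficients, records, truth.

    Returns (records, pedigree, truth) where truth holds the generating
    parameters and per-animal coefficients.
    """
    rng = np.random.default_rng(cfg.seed)
    ped, record_boars = simulate_pedigree(cfg, rng)
    a, pe = simulate_coefficients(ped, cfg.k_a, cfg.k_p, record_boars, rng)
    records = simulate_records(ped, a, pe, cfg, rng,
                               include_first_record=include_first_record)
    truth = {
        "config": cfg.truth_dict(),
        "a_coefficients": {an: a[i].tolist() for i, an in enumerate(ped.animals)},
        "pe_coefficients": {b: v.tolist() for b, v in pe.items()},
    }
    return records, ped, truth


TRUTH_COLUMNS = ("truth_g", "truth_pe", "truth_fixed_age", "truth_aiys",
                 "truth_interval", "truth_resid", "first_record")


def write_records(df: pd.DataFrame, path, schema: str = "date") -> None:
    """Write pipeline input CSV without truth columns.

    schema="date": boar, date, center, trait (ages/intervals re-derived
    downstream from dates and birthdates).
    schema="age": boar, age_weeks, interval_days, center, trait
    (pre-derived convention for date-less extracts).
    """
    trait_cols = [c for c in df.columns
                  if c not in TRUTH_COLUMNS
                  and c not in ("date", "age_weeks", "interval_days", "aiys",
                                "interval_class", "boar", "center")]
    if schema == "date":
        cols = ["boar", "date", "center"] + trait_cols
        out = df[cols].copy()
        out["date"] = pd.to_datetime(out["date"]).dt.date
    elif schema == "age":
        cols = ["boar", "age_weeks", "interval_days", "center"] + trait_cols
        out = df[cols]
    else:
        raise ValueError("schema must be 'date' or 'age'")
    out.to_csv(path, index=False)


def write_pedigree(ped: Pedigree, path) -> None:
    rows = [(a,
             ped.animals[ped.sire[i]] if ped.sire[i] >= 0 else "0",
             ped.animals[ped.dam[i]] if ped.dam[i] >= 0 else "0")
            for i, a in enumerate(ped.animals)]
    pd.DataFrame(rows, columns=["animal", "sire", "dam"]).to_csv(path, index=False)
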