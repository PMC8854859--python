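import numpy as np
import pandas as pd
import pytest

import rrsemen as rr
from rrsemen.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def trio_ped():
    """Sire, dam, and two offspring (one with unknown dam)."""
    return rr.sort_pedigree([("s", None, None), ("d", None, None),
                             ("o1", "s", "d"), ("o2", "s", None)])


def make_small_records(seed: int = 1, n_per_boar: int = 6) -> pd.DataFrame:
    """Tiny derived record table over three boars (oracle-sized)."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in ["o1", "o2", "s"]:
        for _ in range(n_per_boar):
            rows.append(dict(
                boar=b, age_weeks=float(rng.integers(35, 145)), center="C1",
                aiys=f"C1|2015|{1 + rng.integers(0, 3)}", interval_days=7.0,
                interval_class=int(5 + rng.integers(0, 3)),
                vol=250 + rng.normal(0, 50)))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_records():
    return make_small_records()


@pytest.fixture(scope="session")
def small_design(trio_ped, small_records):
    spec = rr.ModelSpec("vol", 1, 1, 1)
    return rr.build_design(small_records, spec, trio_ped,
                           rr.AgeStandardizer(33, 150))


@pytest.fixture(scope="session")
def small_varcomp():
    return rr.VarComp(np.array([[900.0, 100.0], [100.0, 200.0]]),
                      np.array([[700.0, 50.0], [50.0, 100.0]]), 3000.0)


@pytest.fixture(scope="session")
def sim_dataset():
    """Moderate simulated dataset with known truth, QC-filtered, shared
    across estimation tests to keep the suite fast."""
    cfg = SimConfig(seed=42, n_founder_sires=12, n_founder_dams=40,
                    n_gen1_males=60, n_gen1_females=25, n_gen2_males=60,
                    records_per_boar=(10, 18))
    rec, ped, truth = simulate_dataset(cfg)
    rtq, rep = rr.apply_qc(rec, rr.QCConfig(), trait="vol")
    return dict(cfg=cfg, records=rec, filtered=rtq, ped=ped, truth=truth,
                report=rep)


@pytest.fixture(scope="session")
def sim_fit(sim_dataset):
    """One converged REML fit of the generating model on sim_dataset."""
    cfg = sim_dataset["cfg"]
    ped = sim_dataset["ped"]
    d = rr.build_design(sim_dataset["filtered"], rr.ModelSpec("vol", 2, 1, 2),
                        ped, cfg.standardizer())
    ainv = rr.build_nrm_inverse(ped)
    fit = rr.fit_reml(d, ainv, opts=rr.REMLOptions(tol=1e-5, max_iter=150),
                      a_logdet=rr.nrm_logdet(ped))
    return dict(fit=fit, design=d, ainv=ainv)
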