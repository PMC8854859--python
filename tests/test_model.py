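import math

import numpy as np
import pandas as pd
import pytest

import rrsemen as rr
from rrsemen.model import MMEFactor, ModelError, ModelSpec
from rrsemen.pedigree import nrm_logdet
from tests.conftest import make_small_records


def dense_reml_loglik(d, v, A):
    """Independent oracle: REML log-likelihood from the explicit dense V."""
    Z1 = d.Z1.toarray()
    Z2 = d.Z2.toarray()
    X, y = d.X, d.y
    n = len(y)
    mb = len(d.record_boars)
    V = v.sigma_e2 * np.eye(n)
    if v.k_a is not None:
        V += Z1 @ np.kron(A, v.k_a) @ Z1.T
    if v.k_p is not None:
        V += Z2 @ np.kron(np.eye(mb), v.k_p) @ Z2.T
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    return -0.5 * ((n - X.shape[1]) * math.log(2 * math.pi)
                   + np.linalg.slogdet(V)[1] + np.linalg.slogdet(XVX)[1]
                   + y @ P @ y), P, Vi, XVX


class TestModelSpec:
    def test_label_roundtrip(self):
        spec = ModelSpec.from_label("vol", "L(4,3,8)")
        assert (spec.l_fixed, spec.l_additive, spec.l_perm) == (4, 3, 8)
        assert spec.label == "L(4,3,8)"

    def test_count_convention(self):
        spec = ModelSpec.from_label("vol", "L(4,3,8)", convention="count")
        assert (spec.l_fixed, spec.l_additive, spec.l_perm) == (3, 2, 7)

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("vol", -1, 0, 0)


class TestBuildDesign:
    def test_single_record_intercept_model(self, trio_ped):
        rt = pd.DataFrame([dict(boar="o1", age_weeks=90.0, center="C1",
                                aiys="A", interval_days=7.0, interval_class=7,
                                vol=250.0)])
        d = rr.build_design(rt, ModelSpec("vol", 0, 0, 0), trio_ped,
                            rr.AgeStandardizer(33, 150))
        Z1 = d.Z1.toarray()
        col = d.animals.index("o1")
        assert Z1[0, col] == pytest.approx(np.sqrt(0.5), abs=1e-4)
        assert np.count_nonzero(Z1) == 1

    def test_fixed_regression_rows_at_window_edges(self, trio_ped):
        rt = pd.DataFrame([
            dict(boar="o1", age_weeks=33.0, center="C1", aiys="A",
                 interval_days=7.0, interval_class=7, vol=250.0),
            dict(boar="o1", age_weeks=150.0, center="C1", aiys="A",
                 interval_days=7.0, interval_class=7, vol=260.0)])
        d = rr.build_design(rt, ModelSpec("vol", 1, None, None), trio_ped,
                            rr.AgeStandardizer(33, 150))
        assert d.X2[0] == pytest.approx([0.7071, -1.2247], abs=1e-4)
        assert d.X2[1] == pytest.approx([0.7071, 1.2247], abs=1e-4)

    def test_incidence_column_sums_match_level_counts(self, trio_ped):
        rt = make_small_records(seed=2, n_per_boar=3)
        d = rr.build_design(rt, ModelSpec("vol", 1, 1, 1), trio_ped,
                            rr.AgeStandardizer(33, 150))
        sums = d.X1.sum(axis=0)
        for (factor, level), got in zip(d.x1_labels, sums):
            assert got == (rt[factor] == level).sum()

    def test_boar_missing_from_pedigree(self, trio_ped):
        rt = pd.DataFrame([dict(boar="ghost", age_weeks=90.0, center="C1",
                                aiys="A", interval_days=7.0, interval_class=7,
                                vol=250.0)])
        with pytest.raises(ModelError, match="ghost"):
            rr.build_design(rt, ModelSpec("vol", 0, 0, 0), trio_ped,
                            rr.AgeStandardizer(33, 150))


class TestRestrictedLoglik:
    def test_matches_dense_mvn_oracle(self, trio_ped, small_design,
                                      small_varcomp):
        A = rr.build_nrm(trio_ped)
        ainv = rr.build_nrm_inverse(trio_ped)
        ll = rr.restricted_loglik(small_design, small_varcomp, ainv,
                                  nrm_logdet(trio_ped))
        ll0, _, _, _ = dense_reml_loglik(small_design, small_varcomp, A)
        assert ll == pytest.approx(ll0, abs=1e-6)

    def test_zero_k_equals_fixed_effects_closed_form(self, trio_ped,
                                                     small_design):
        ainv = rr.build_nrm_inverse(trio_ped)
        sig = 3000.0
        ll = rr.restricted_loglik(small_design, rr.VarComp(None, None, sig),
                                  ainv)
        X, y = small_design.X, small_design.y
        n, p = X.shape
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ beta) ** 2).sum())
        ll0 = -0.5 * ((n - p) * math.log(2 * math.pi) + n * math.log(sig)
                      + np.linalg.slogdet(X.T @ X / sig)[1] + rss / sig)
        assert ll == pytest.approx(ll0, abs=1e-8)
        # all-zero K matrices behave exactly like absent terms
        llz = rr.restricted_loglik(
            small_design, rr.VarComp(np.zeros((2, 2)), np.zeros((2, 2)), sig),
            ainv)
        assert llz == ll

    def test_scaling_identity(self, trio_ped, small_design, small_varcomp):
        """Scaling y by sqrt(2) and all variances by 2 shifts the REML
        log-likelihood by exactly -(n - p)/2 * log 2."""
        ainv = rr.build_nrm_inverse(trio_ped)
        ald = nrm_logdet(trio_ped)
        ll1 = rr.restricted_loglik(small_design, small_varcomp, ainv, ald)
        import copy
        d2 = copy.copy(small_design)
        d2.y = small_design.y * np.sqrt(2)
        d2._ws = None
        v2 = rr.VarComp(2 * small_varcomp.k_a, 2 * small_varcomp.k_p,
                        2 * small_varcomp.sigma_e2)
        ll2 = rr.restricted_loglik(d2, v2, ainv, ald)
        n, p = small_design.X.shape
        assert ll2 == pytest.approx(ll1 - 0.5 * (n - p) * math.log(2),
                                    abs=1e-8)

    def test_invariant_to_reference_level_choice(self, trio_ped,
                                                 small_records,
                                                 small_varcomp):
        ainv = rr.build_nrm_inverse(trio_ped)
        ald = nrm_logdet(trio_ped)
        s = rr.AgeStandardizer(33, 150)
        spec = ModelSpec("vol", 1, 1, 1)
        d1 = rr.build_design(small_records, spec, trio_ped, s)
        relabeled = small_records.copy()
        relabeled["aiys"] = relabeled["aiys"].map(
            lambda x: "zz" if x.endswith("1") else x)  # new reference level
        d2 = rr.build_design(relabeled, spec, trio_ped, s)
        assert d1.reference_levels["aiys"] != d2.reference_levels["aiys"]
        ll1 = rr.restricted_loglik(d1, small_varcomp, ainv, ald)
        ll2 = rr.restricted_loglik(d2, small_varcomp, ainv, ald)
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_invariant_to_record_order(self, trio_ped, small_records,
                                       small_varcomp):
        ainv = rr.build_nrm_inverse(trio_ped)
        ald = nrm_logdet(trio_ped)
        s = rr.AgeStandardizer(33, 150)
        spec = ModelSpec("vol", 1, 1, 1)
        d1 = rr.build_design(small_records, spec, trio_ped, s)
        perm = small_records.sample(frac=1, random_state=7).reset_index(drop=True)
        d2 = rr.build_design(perm, spec, trio_ped, s)
        ll1 = rr.restricted_loglik(d1, small_varcomp, ainv, ald)
        ll2 = rr.restricted_loglik(d2, small_varcomp, ainv, ald)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_non_psd_varcomp_rejected(self, trio_ped, small_design):
        ainv = rr.build_nrm_inverse(trio_ped)
        bad = rr.VarComp(np.array([[1.0, 2.0], [2.0, 1.0]]),
                         np.eye(2), 100.0)
        with pytest.raises(ModelError, match="positive semi-definite"):
            rr.restricted_loglik(small_design, bad, ainv)


class TestSolveMME:
    def test_fixed_effects_match_gls_oracle(self, trio_ped, small_design,
                                            small_varcomp):
        A = rr.build_nrm(trio_ped)
        ainv = rr.build_nrm_inverse(trio_ped)
        _, P, Vi, XVX = dense_reml_loglik(small_design, small_varcomp, A)
        fac = MMEFactor(small_design, small_varcomp, ainv, nrm_logdet(trio_ped))
        b_gls = np.linalg.solve(XVX, small_design.X.T @ Vi @ small_design.y)
        assert np.abs(fac.b - b_gls).max() < 1e-8

    def test_blups_match_dense_oracle(self, trio_ped, small_design,
                                      small_varcomp):
        A = rr.build_nrm(trio_ped)
        ainv = rr.build_nrm_inverse(trio_ped)
        _, P, _, _ = dense_reml_loglik(small_design, small_varcomp, A)
        sol = rr.solve_mme(small_design, small_varcomp, ainv,
                           nrm_logdet(trio_ped))
        Z1 = small_design.Z1.toarray()
        Z2 = small_design.Z2.toarray()
        mb = len(small_design.record_boars)
        a0 = np.kron(A, small_varcomp.k_a) @ Z1.T @ P @ small_design.y
        p0 = np.kron(np.eye(mb), small_varcomp.k_p) @ Z2.T @ P @ small_design.y
        assert np.abs(sol.a_hat.to_numpy().ravel() - a0).max() < 1e-8
        assert np.abs(sol.p_hat.to_numpy().ravel() - p0).max() < 1e-8

    def test_shrinkage_to_zero_with_tiny_k(self, trio_ped, small_design):
        ainv = rr.build_nrm_inverse(trio_ped)
        tiny = rr.VarComp(1e-6 * np.eye(2), None, 3000.0)
        sol = rr.solve_mme(small_design, tiny, ainv)
        assert np.abs(sol.a_hat.to_numpy()).max() < 1e-3

    def test_offspring_record_moves_sire_same_direction(self):
        ped = rr.sort_pedigree([("s", None, None), ("d", None, None),
                                ("o1", "s", "d"), ("o2", "s", "d")])
        rows = [dict(boar=b, age_weeks=90.0 + k, center="C1", aiys="A",
                     interval_days=7.0, interval_class=7, vol=250.0)
                for b in ("o1", "o2") for k in range(3)]
        rt = pd.DataFrame(rows)
        rt.loc[rt["boar"] == "o1", "vol"] = 300.0  # o1 well above the mean
        d = rr.build_design(rt, ModelSpec("vol", 0, 0, 0), ped,
                            rr.AgeStandardizer(33, 150))
        sol = rr.solve_mme(d, rr.VarComp(np.array([[400.0]]), None, 900.0),
                           rr.build_nrm_inverse(ped))
        a = sol.a_hat[0]
        assert a["o1"] > 0
        assert a["s"] > 0 and np.sign(a["s"]) == np.sign(a["o1"])
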