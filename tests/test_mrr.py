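import numpy as np
import pytest

from msipm.config import StudyConfig
from msipm.data import MRRSufficientStats
from msipm.likelihoods.cjs import cjs_chi
from msipm.likelihoods.mrr import (
    MRRStructuralParams,
    _compute_mrr_tables_numpy,
    assemble_age_year_params,
    compute_mrr_tables,
    mrr_cohort_cell_probs,
    mrr_loglik,
    standardized_years,
)
from msipm.util import expit

from .oracles import mrr_enum_cell_probs


def random_tables_params(A, T, rng, lam_hi=0.3):
    """Random fully age/year-dependent parameter tables (1-based, zero pad)."""
    phi = np.zeros((A + 1, T + 1))
    F = np.zeros((A + 1, T + 1))
    lam = np.zeros((A + 1, T + 1))
    p = np.zeros((A + 1, T + 1))
    phi[1:, 1:T] = rng.uniform(0.2, 0.95, (A, T - 1))
    F[1:, 1:T] = rng.uniform(0.3, 1.0, (A, T - 1))
    lam[1:, 1:T] = rng.uniform(0.0, lam_hi, (A, T - 1))
    p[1:, 2:] = rng.uniform(0.05, 0.9, (A, T - 1))
    return phi, F, p, lam


def structural(config, rng, constant_p=None):
    T = config.T
    p = {}
    for area in config.areas:
        p[area] = {}
        for cls in ("p2", "p3", "p45", "pa"):
            lo, hi = config.window(area, cls)
            arr = np.full(T + 1, np.nan)
            arr[lo : hi + 1] = (
                constant_p if constant_p is not None else rng.uniform(0.1, 0.7, hi - lo + 1)
            )
            p[area][cls] = arr
    return MRRStructuralParams(
        s1=np.concatenate([[np.nan], rng.uniform(0.2, 0.8, T - 1), [np.nan]]),
        s2=0.76,
        s35=0.9,
        s_a=np.concatenate([[np.nan], rng.uniform(0.85, 0.95, T - 1), [np.nan]]),
        F5=0.87,
        F6=0.83,
        psi=0.85,
        alpha0=-2.5,
        alpha1=-0.5,
        p=p,
    )


class TestAssembly:
    def test_age_structure(self, rng):
        cfg = StudyConfig.reduced(T=12)
        st = structural(cfg, rng)
        phi, F, lam, p = assemble_age_year_params(st, cfg)
        ts = slice(1, cfg.T)
        assert np.all(F[1:5, ts] == 1.0)  # no pre-recruitment emigration below age 5
        assert np.all(F[5, ts] == st.F5) and np.all(F[6, ts] == st.F6)
        assert np.all(F[7:, ts] == st.psi)
        assert np.all(p["A"][1:3, :] == 0.0)  # no resights in first two ages
        assert np.allclose(phi[1, ts], st.s1[ts])
        assert np.allclose(phi[7, ts], st.s_a[ts])

    def test_constant_reporting_when_trend_zero(self, rng):
        cfg = StudyConfig.reduced(T=10)
        st = structural(cfg, rng)
        st.alpha1 = 0.0
        _, _, lam, _ = assemble_age_year_params(st, cfg)
        vals = lam[1:, 1 : cfg.T - 1]
        assert np.allclose(vals, expit(st.alpha0))

    def test_reporting_trend_uses_standardized_years(self, rng):
        cfg = StudyConfig.reduced(T=10)
        st = structural(cfg, rng)
        _, _, lam, _ = assemble_age_year_params(st, cfg)
        y = standardized_years(cfg.T)
        assert lam[3, 4] == pytest.approx(expit(st.alpha0 + st.alpha1 * y[4]))
        # sample standardization: mean 0, sd 1
        assert np.nanmean(y[1:]) == pytest.approx(0.0, abs=1e-12)
        assert np.nanstd(y[1 : cfg.T], ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestTables:
    def test_chi_is_one_at_final_occasion(self, rng):
        A = T = 7
        tables = compute_mrr_tables(*random_tables_params(A, T, rng), A, T)
        assert np.all(tables.chi1[:, T] == 1.0)
        assert np.all(tables.chi0[:, T] == 1.0)

    def test_first_step_probability(self, rng):
        A = T = 6
        phi, F, p, lam = random_tables_params(A, T, rng)
        tables = compute_mrr_tables(phi, F, p, lam, A, T)
        assert tables.Q11[0, 3, 2] == pytest.approx(phi[3, 2] * F[3, 2], abs=1e-14)

    def test_kernel_matches_numpy_path(self, rng):
        A = T = 9
        phi, F, p, lam = random_tables_params(A, T, rng)
        t1 = compute_mrr_tables(phi, F, p, lam, A, T)
        t2 = _compute_mrr_tables_numpy(phi, F, p, lam, A, T)
        for nm in ("Q11", "Q10", "Q00", "O", "D", "chi1", "chi0"):
            assert np.allclose(getattr(t1, nm), getattr(t2, nm), atol=1e-14), nm

    def test_chi_reduces_to_cjs_without_emigration_or_recovery(self, rng):
        """With F=1 and lambda=0 the two-state chi collapses onto the classic
        CJS never-seen-again probability."""
        A = T = 8
        s = rng.uniform(0.3, 0.95, T - 1)
        pr = rng.uniform(0.1, 0.9, T - 1)
        phi = np.zeros((A + 1, T + 1))
        F = np.zeros((A + 1, T + 1))
        lam = np.zeros((A + 1, T + 1))
        p = np.zeros((A + 1, T + 1))
        phi[1:, 1:T] = s[None, :]
        F[1:, 1:T] = 1.0
        p[1:, 2:] = pr[None, :]
        tables = compute_mrr_tables(phi, F, p, lam, A, T)
        s1 = np.concatenate([[np.nan], s, [np.nan]])
        p1 = np.concatenate([[np.nan, np.nan], pr])
        chi_seen, chi_not = cjs_chi(s1, p1, p1)
        for a in range(1, A + 1):
            for t in range(a, T + 1):
                assert tables.chi1[a, t] == pytest.approx(chi_not[t], abs=1e-12)


class TestCohortCells:
    def test_cells_match_exhaustive_enumeration(self, rng):
        for _ in range(12):
            A = T = int(rng.integers(4, 6))
            phi, F, p, lam = random_tables_params(A, T, rng)
            tables = compute_mrr_tables(phi, F, p, lam, A, T)
            for a0 in range(1, A + 1):
                for t0 in range(a0, T + 1):
                    O, D, chi = mrr_enum_cell_probs(a0, t0, phi, F, p, lam, A, T)
                    got = mrr_cohort_cell_probs(a0, t0, tables)
                    want = np.concatenate([O, D, [chi]])
                    assert np.allclose(got, want, atol=1e-12)

    def test_cells_sum_to_one(self, rng):
        for _ in range(30):
            A = T = int(rng.integers(4, 9))
            tables = compute_mrr_tables(*random_tables_params(A, T, rng), A, T)
            for a0 in range(1, A + 1):
                for t0 in range(a0, T + 1):
                    assert mrr_cohort_cell_probs(a0, t0, tables).sum() == pytest.approx(
                        1.0, abs=1e-10
                    )

    def test_unobservable_parameters_leave_only_chi(self, rng):
        A = T = 5
        phi, F, p, lam = random_tables_params(A, T, rng)
        p[:] = 0.0
        lam[:] = 0.0
        tables = compute_mrr_tables(phi, F, p, lam, A, T)
        cells = mrr_cohort_cell_probs(1, 1, tables)
        assert cells[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(cells[:-1], 0.0)

    def test_recovery_cells_monotone_in_reporting(self, rng):
        A = T = 6
        phi, F, p, lam = random_tables_params(A, T, rng, lam_hi=0.2)
        t_lo = compute_mrr_tables(phi, F, p, lam, A, T)
        lam_hi = np.clip(lam * 2.0, 0.0, 1.0)
        t_hi = compute_mrr_tables(phi, F, p, lam_hi, A, T)
        assert np.all(t_hi.D >= t_lo.D - 1e-15)


class TestLikelihood:
    def test_all_zero_stats_score_zero(self, rng):
        cfg = StudyConfig.reduced(T=10)
        st = structural(cfg, rng)
        sA = MRRSufficientStats.zeros("A", cfg.A, cfg.T)
        sB = MRRSufficientStats.zeros("B", cfg.A, cfg.T)
        assert mrr_loglik(sA, sB, st, cfg) == 0.0

    def test_single_bird_equals_log_cell_probability(self, rng):
        cfg = StudyConfig.reduced(T=10)
        st = structural(cfg, rng)
        sA = MRRSufficientStats.zeros("A", cfg.A, cfg.T)
        sB = MRRSufficientStats.zeros("B", cfg.A, cfg.T)
        # one chick released in area A at t0=2, resighted once at age 4 (t=5)
        sA.n[1, 3, 2] = 1
        sA.v[4, 5] = 1
        phi, F, lam, p = assemble_age_year_params(st, cfg)
        tables = compute_mrr_tables(phi, F, p["A"], lam, cfg.A, cfg.T)
        want = np.log(tables.O_cell(1, 3, 2)) + np.log(tables.chi_cell(4, 5))
        assert mrr_loglik(sA, sB, st, cfg) == pytest.approx(want, abs=1e-10)

    def test_positive_count_on_impossible_cell_is_minus_inf(self, rng):
        cfg = StudyConfig.reduced(T=10)
        st = structural(cfg, rng, constant_p=0.3)
        sA = MRRSufficientStats.zeros("A", cfg.A, cfg.T)
        sB = MRRSufficientStats.zeros("B", cfg.A, cfg.T)
        sA.n[1, 1, 1] = 1  # next seen alive at age 2: resight probability is zero
        sA.v[2, 2] = 1
        assert mrr_loglik(sA, sB, st, cfg) == -np.inf
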