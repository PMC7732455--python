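import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import comb

from neoplasma.diffabund import (
    PairedDifferentialModel,
    adjust_bh,
    call_significance,
    fisher_missingness,
    fit_paired_lmm,
)
from neoplasma.simulate import SimConfig, generate_cohort

from conftest import make_matrix, make_paired_meta


def bh_bruteforce(p):
    """O(m^2) definitional oracle: q_i = min over p_(j) >= p_i of p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [p[j] * m / ranks[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(min(candidates), 1.0)
    return q


def fisher_enumeration(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1, exact=True)
    p_obs = comb(r1, a, exact=True) * comb(r2, c1 - a, exact=True) / denom
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / denom
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


class TestAdjustBH:
    def test_hand_computed_stepup(self):
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(adjust_bh(p), bh_bruteforce(p), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25),
           st.data())
    def test_monotone_in_input(self, p, data):
        """Increasing any single p never decreases any q."""
        i = data.draw(st.integers(0, len(p) - 1))
        bump = data.draw(st.floats(0, 1))
        p2 = list(p)
        p2[i] = min(1.0, p2[i] + bump)
        q1, q2 = adjust_bh(p), adjust_bh(p2)
        assert (q2 >= q1 - 1e-12).all()


class TestPairedModel:
    def _clean_arm(self, seed=0, n=12, beta=0.0, sd=0.3):
        rng = np.random.default_rng(seed)
        meta = make_paired_meta((n, 0, 0))
        u = rng.normal(0, 0.5, n)
        vals = np.empty((5, 2 * n))
        for j, (_, row) in enumerate(meta.iterrows()):
            p = int(row.participant_id[1:]) - 1
            vals[:, j] = 24 + u[p] + beta * (row.dol == 1) + rng.normal(0, sd, 5)
        return make_matrix(vals, sample_ids=meta["sample_id"].tolist()), meta

    def test_beta_equals_mean_paired_difference_exactly(self):
        """Balanced complete pairs, no covariates: the model coefficient is
        the mean within-participant difference."""
        m, meta = self._clean_arm(seed=1, beta=0.4)
        res = fit_paired_lmm(m, meta, 1, covariates=())
        f = res.frame
        assert np.allclose(f["log2fc"], f["paired_mean_diff"], atol=1e-9)

    def test_constant_intensities_give_zero_fc_p_one(self):
        meta = make_paired_meta((6, 0, 0))
        m = make_matrix(np.full((4, 12), 22.0), sample_ids=meta["sample_id"].tolist())
        res = fit_paired_lmm(m, meta, 1, covariates=())
        assert np.allclose(res.frame["log2fc"], 0.0)
        assert (res.frame["p_lrt"] > 0.999).all()

    def test_parameter_recovery(self):
        """True day effect 0.8 at n=30 pairs, residual sd 0.3: estimates land
        within +/-0.15 of truth at close to the theoretical 94.7% rate
        (the +/-0.15 band is 1.94 standard errors of a 30-pair mean)."""
        errs = []
        for seed in range(60):
            m, meta = self._clean_arm(seed=100 + seed, n=30, beta=0.8)
            res = fit_paired_lmm(m, meta, 1, covariates=())
            errs.append(res.frame["log2fc"].to_numpy() - 0.8)
        errs = np.concatenate(errs)
        assert np.abs(np.mean(errs)) < 0.02          # unbiased
        assert (np.abs(errs) <= 0.15).mean() >= 0.90  # approx 94.7% in theory

    def test_sign_matches_paired_difference(self, clean_cohort):
        matrix, _, meta, _ = clean_cohort
        res = fit_paired_lmm(matrix, meta, 7, covariates=())
        f = res.frame.dropna(subset=["log2fc"])
        nonzero = f[np.abs(f["paired_mean_diff"]) > 1e-12]
        assert (np.sign(nonzero["log2fc"]) == np.sign(nonzero["paired_mean_diff"])).all()

    def test_imputed_matrix_refused(self, default_cohort):
        from neoplasma.ordination import ImputationParams, impute_left_censored
        matrix, _, meta, _ = default_cohort
        imputed = impute_left_censored(matrix, ImputationParams(seed=0))
        with pytest.raises(ValueError, match="unimputed"):
            PairedDifferentialModel(imputed, meta, 1)

    def test_generator_truth_recovered(self, clean_cohort):
        """Significant calls enrich for truly regulated proteins."""
        matrix, _, meta, truth = clean_cohort
        res = fit_paired_lmm(matrix, meta, 7)
        f = res.frame.set_index("protein")
        t = truth.protein_effects.set_index("protein").loc[f.index]
        sig_true_fc = np.abs(t.loc[f["significant"], "lfc_dol7"])
        assert res.n_significant > 0
        assert (sig_true_fc > 0).mean() > 0.9


class TestSignificanceGate:
    def _result(self, q, lfc):
        frame = pd.DataFrame(
            {"protein": ["x"], "gene": [""], "dol": 1, "log2fc": [lfc],
             "se": [0.1], "paired_mean_diff": [lfc], "p_lrt": [q], "q_value": [q],
             "significant": [False], "n_pairs": [10], "n_obs": [20],
             "sigma2_u": [0.1], "sigma2_e": [0.1], "not_testable": [False]}
        )
        from neoplasma.diffabund import DifferentialResults
        return DifferentialResults(frame, 1, 0.05, 0.2, ["intercept", "dol1"])

    @pytest.mark.parametrize(
        "q,lfc,expected",
        [(0.04, 0.19, False), (0.04, -0.5, True), (0.06, 1.0, False)],
    )
    def test_dual_gate(self, q, lfc, expected):
        res = call_significance(self._result(q, lfc))
        assert bool(res.frame["significant"][0]) is expected


class TestFisherMissingness:
    def test_complete_separation_matches_enumeration(self):
        """Detected 10/10 at DOL0 and 0/10 at DOL7: p = 2/C(20,10)."""
        meta = make_paired_meta((0, 0, 10))
        vals = np.full((1, 20), 22.0)
        m = make_matrix(vals, sample_ids=meta["sample_id"].tolist())
        d7 = meta.loc[meta.dol == 7, "sample_id"]
        m.lfq.loc["P001", d7] = np.nan
        res = fisher_missingness(m, meta, 7)
        expected = 2 / comb(20, 10, exact=True)
        assert res.frame["p_fisher"][0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1.0824e-5, rel=1e-3)

    def test_identical_detection_gives_p_one(self):
        meta = make_paired_meta((4, 0, 0))
        m = make_matrix(np.full((2, 8), 20.0), sample_ids=meta["sample_id"].tolist())
        res = fisher_missingness(m, meta, 1)
        assert (res.frame["p_fisher"] == 1.0).all()

    def test_matches_enumeration_small_margins(self):
        """All 2x2 tables with margins <= 12 agree with the enumeration
        oracle."""
        for n0 in range(1, 7):
            for n1 in range(1, 7):
                for a in range(n0 + 1):
                    for b in range(n1 + 1):
                        table = [[a, n0 - a], [b, n1 - b]]
                        p_impl = stats.fisher_exact(table)[1]
                        p_oracle = fisher_enumeration(table)
                        assert p_impl == pytest.approx(p_oracle, rel=1e-9, abs=1e-12)

    def test_table_margins_equal_arm_counts(self, default_cohort):
        matrix, _, meta, _ = default_cohort
        res = fisher_missingness(matrix, meta, 3)
        n0 = ((meta.dol == 0) & meta.participant_id.isin(
            meta.loc[meta.dol == 3, "participant_id"])).sum()
        n3 = (meta.dol == 3).sum()
        f = res.frame
        assert ((f["det_dol0"] + f["undet_dol0"]) == n0).all()
        assert ((f["det_dolx"] + f["undet_dolx"]) == n3).all()
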