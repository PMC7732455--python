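import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neoplasma.immunoglobulin import (
    HalfLifeModel,
    compare_ratios,
    compute_ig_ratios,
    correlate_pair,
    estimate_half_life,
    project_concentration,
    synthetic_adult_panel,
)
from neoplasma.simulate import SimConfig, generate_cohort
from neoplasma.trajectories import compute_changes


def _noise_free_cohort(t_half=21.1, seed=2):
    from neoplasma.simulate import IgSpec, default_ig_panel
    panel = default_ig_panel()
    panel["IGHG1"] = IgSpec(baseline_ibaq=4.0e9, half_life_days=t_half)
    cfg = SimConfig(seed=seed, n_proteins=5, n_participants=6, followup_split=(2, 2, 2),
                    residual_sd=0.0, censor_quantile=0.0,
                    batch_effects={"b": (0.0, 1.0)},
                    trajectory_classes={"flat": 1.0}, ig_panel=panel)
    return generate_cohort(cfg)


class TestIgRatios:
    def test_reference_ratio_is_one(self, clean_cohort):
        matrix, _, meta, _ = clean_cohort
        panel = compute_ig_ratios(matrix, meta)
        assert np.allclose(panel.ratios["IGHG2"].dropna(), 1.0)

    def test_configured_ratio_recovered(self, clean_cohort):
        """Generator IgG1:IgG2 baseline 4:1 shows up in the mean ratio."""
        matrix, _, meta, _ = clean_cohort
        panel = compute_ig_ratios(matrix, meta)
        dol0 = meta.loc[meta.dol == 0, "sample_id"]
        r1 = panel.ratios.loc[dol0, "IGHG1"].mean()
        assert r1 == pytest.approx(4.0, rel=0.25)

    def test_reference_switch_preserves_ordering(self, clean_cohort):
        matrix, _, meta, _ = clean_cohort
        p2 = compute_ig_ratios(matrix, meta, ref="IGHG2")
        p3 = compute_ig_ratios(matrix, meta, ref="IGHG3")
        order2 = p2.ratios[list(("IGHG1", "IGHG2", "IGHG3", "IGHG4"))].mean().sort_values()
        order3 = p3.ratios[list(("IGHG1", "IGHG2", "IGHG3", "IGHG4"))].mean().sort_values()
        assert list(order2.index) == list(order3.index)

    def test_renormalization_is_change_of_units(self, clean_cohort):
        """r_k^(ref2) = r_k^(ref1) / r_ref2^(ref1) exactly."""
        matrix, _, meta, _ = clean_cohort
        p2 = compute_ig_ratios(matrix, meta, ref="IGHG2")
        p3 = compute_ig_ratios(matrix, meta, ref="IGHG3")
        derived = p2.ratios.div(p2.ratios["IGHG3"], axis=0)
        assert np.allclose(derived.to_numpy(), p3.ratios.to_numpy(), equal_nan=True)

    def test_missing_ibaq_rejected(self, clean_cohort):
        matrix = clean_cohort[0].copy()
        matrix.ibaq = None
        with pytest.raises(ValueError, match="iBAQ"):
            compute_ig_ratios(matrix)


class TestCompareRatios:
    def test_identical_panels_null(self):
        adult = synthetic_adult_panel(seed=1)
        res = compare_ratios(adult, adult).set_index("subclass")
        assert (res["p"] > 0.999).all()
        assert np.allclose(res["t"], 0.0)

    def test_newborn_igg1_elevation_detected(self, clean_cohort):
        matrix, _, meta, _ = clean_cohort
        newborn = compute_ig_ratios(matrix, meta)
        adult = synthetic_adult_panel()
        res = compare_ratios(newborn, adult).set_index("subclass")
        assert res.loc["IGHG1", "p"] < 0.01
        assert res.loc["IGHG1", "mean_newborn"] > res.loc["IGHG1", "mean_adult"]

    def test_welch_type_one_error_calibrated(self):
        """Equal means with unequal variances: rejection rate near alpha."""
        rng = np.random.default_rng(0)
        rej = 0
        N = 1000
        for _ in range(N):
            a = rng.normal(0, 1, 25)
            b = rng.normal(0, 3, 40)
            from scipy import stats
            rej += stats.ttest_ind(a, b, equal_var=False)[1] < 0.05
        assert 0.03 < rej / N < 0.07


class TestHalfLife:
    def test_exact_on_noise_free_decay(self):
        matrix, _, meta, _ = _noise_free_cohort()
        traj = compute_changes(matrix, meta)
        res = estimate_half_life(traj, "IG_IGHG1", bootstrap_n=0)
        assert res.t_half == pytest.approx(21.1, abs=1e-9)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.floats(5, 60))
    def test_exact_for_any_half_life(self, t_half):
        matrix, _, meta, _ = _noise_free_cohort(t_half=t_half)
        traj = compute_changes(matrix, meta)
        res = estimate_half_life(traj, "IG_IGHG1", bootstrap_n=0)
        assert res.t_half == pytest.approx(t_half, rel=1e-9)

    def test_no_decay_flags_infinite(self):
        meta_cohort = _noise_free_cohort()
        matrix, _, meta, _ = meta_cohort
        traj = compute_changes(matrix, meta)
        traj.delta.loc["PROT0001"] = 0.0
        res = estimate_half_life(traj, "PROT0001", bootstrap_n=0)
        assert np.isinf(res.t_half)
        assert not res.decaying

    def test_scale_invariance(self, clean_cohort):
        """Adding a constant to all log2 intensities leaves t_half fixed."""
        matrix, _, meta, _ = clean_cohort
        traj = compute_changes(matrix, meta)
        shifted = matrix.copy()
        shifted.lfq = shifted.lfq + 3.7
        traj2 = compute_changes(shifted, meta)
        a = estimate_half_life(traj, "IG_IGHG1", bootstrap_n=0)
        b = estimate_half_life(traj2, "IG_IGHG1", bootstrap_n=0)
        assert a.t_half == pytest.approx(b.t_half, rel=1e-12)

    def test_bootstrap_ci_contains_estimate_and_is_seeded(self, clean_cohort):
        matrix, _, meta, _ = clean_cohort
        traj = compute_changes(matrix, meta)
        a = estimate_half_life(traj, "IG_IGHG1", bootstrap_n=500, seed=1)
        b = estimate_half_life(traj, "IG_IGHG1", bootstrap_n=500, seed=1)
        assert a.t_half_ci == b.t_half_ci
        assert a.t_half_ci[0] <= a.t_half <= a.t_half_ci[1]

    def test_single_day_flagged(self):
        from neoplasma.simulate import SimConfig, generate_cohort
        cfg = SimConfig(seed=2, n_proteins=5, n_participants=6, followup_split=(4, 1, 1),
                        residual_sd=0.0, censor_quantile=0.0,
                        batch_effects={"b": (0.0, 1.0)}, trajectory_classes={"flat": 1.0})
        matrix, _, meta, _ = generate_cohort(cfg)
        meta1 = meta[meta.participant_id.isin(
            meta.loc[meta.dol == 1, "participant_id"])]
        traj = compute_changes(matrix, meta1.reset_index(drop=True))
        model = HalfLifeModel(traj, "IG_IGHG1")
        res = model.fit(bootstrap_n=0)
        assert res.single_day
        assert res.t_half > 0


class TestProjection:
    def test_interval_projection_matches_hand_computation(self):
        """Baseline 18.5 mg/dl with fold interval [2.054, 2.919] projects to
        38-54 mg/dl."""
        out = project_concentration(18.5, [2.054, 2.919])
        assert out[0] == pytest.approx(38.0, abs=0.01)
        assert out[1] == pytest.approx(54.0, abs=0.01)

    def test_unit_fold_is_identity(self):
        assert project_concentration(18.5, 1.0) == pytest.approx(18.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            project_concentration(-1.0, 2.0)
        with pytest.raises(ValueError):
            project_concentration(18.5, 0.0)


class TestCorrelatePair:
    def test_self_correlation_is_one(self, clean_cohort):
        matrix, _, meta, _ = clean_cohort
        traj = compute_changes(matrix, meta)
        r, p = correlate_pair(traj, "IG_IGHM", "IG_IGHM")
        assert r == pytest.approx(1.0)

    def test_igm_jchain_coupled_growth(self, clean_cohort):
        """Shared latent growth couples IgM and J chain trajectories."""
        matrix, _, meta, _ = clean_cohort
        traj = compute_changes(matrix, meta)
        r, p = correlate_pair(traj, "IG_IGHM", "IG_JCHAIN")
        assert r > 0.6
        assert p < 0.01

    def test_anticoupled_pair_negative(self):
        matrix, _, meta, _ = _noise_free_cohort()
        traj = compute_changes(matrix, meta)
        traj.delta.loc["PROT0001"] = -traj.delta.loc["IG_IGHM"]
        r, _ = correlate_pair(traj, "IG_IGHM", "PROT0001")
        assert r == pytest.approx(-1.0)
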