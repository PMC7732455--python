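import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from neoplasma.io import DesignError
from neoplasma.preprocess import (
    correct_batch,
    filter_flags,
    filter_valid_values,
    filter_valid_values_union,
    test_global_distributions as global_distribution_test,
)
from neoplasma.simulate import SimConfig, generate_cohort

from conftest import make_matrix, make_paired_meta


class TestFilterFlags:
    def test_identity_when_no_flags(self, clean_cohort):
        matrix = clean_cohort[0]
        out, report = filter_flags(matrix)
        assert out.lfq.equals(matrix.lfq)
        assert report.n_quantifiable == matrix.n_proteins

    def test_double_flag_counted_once_as_contaminant(self):
        m = make_matrix(np.ones((3, 2)) * 20)
        m.records.loc["P001", ["is_contaminant", "is_reverse"]] = True
        m.records.loc["P002", "is_reverse"] = True
        out, report = filter_flags(m)
        assert report.n_removed_contaminant == 1
        assert report.n_removed_reverse == 1
        assert out.n_proteins == 1


class TestFilterValidValues:
    def _setup(self, present0, present1, n=10):
        """One protein observed in present0/n DOL0 and present1/n DOL1 samples."""
        meta = make_paired_meta((n, 0, 0))
        vals = np.full((1, 2 * n), 20.0)
        s0 = meta[meta.dol == 0]["sample_id"].tolist()
        s1 = meta[meta.dol == 1]["sample_id"].tolist()
        cols = s0 + s1
        m = make_matrix(vals, sample_ids=cols)
        for s in s0[present0:]:
            m.lfq.loc["P001", s] = np.nan
        for s in s1[present1:]:
            m.lfq.loc["P001", s] = np.nan
        return m, meta

    def test_below_half_in_one_group_removed(self):
        m, meta = self._setup(10, 4)
        out, report = filter_valid_values(m, meta, 1)
        assert out.n_proteins == 0
        assert report.n_removed_valid_value[1] == 1

    def test_fully_observed_retained(self):
        m, meta = self._setup(10, 10)
        out, _ = filter_valid_values(m, meta, 1)
        assert out.n_proteins == 1

    def test_exactly_half_retained(self):
        """The less-than-50% rule is exclusive: exactly 50% stays."""
        m, meta = self._setup(5, 5)
        out, _ = filter_valid_values(m, meta, 1)
        assert out.n_proteins == 1

    def test_never_creates_values(self, default_cohort):
        matrix, _, meta, _ = default_cohort
        out, _ = filter_valid_values(matrix, meta, 3)
        sub = matrix.lfq.loc[out.lfq.index]
        assert out.lfq.equals(sub)

    def test_empty_arm_is_design_error(self):
        m, meta = self._setup(10, 10)
        with pytest.raises(DesignError):
            filter_valid_values(m, meta, 7)

    def test_union_filter_is_superset_of_each_arm(self, default_cohort):
        matrix, _, meta, _ = default_cohort
        union, _ = filter_valid_values_union(matrix, meta)
        for dol in (1, 3, 7):
            arm, _ = filter_valid_values(matrix, meta, dol)
            assert set(arm.records.index) <= set(union.records.index)


class TestCorrectBatch:
    def _cohort(self, seed=11, **kw):
        cfg = SimConfig(seed=seed, n_proteins=200, trajectory_classes={"flat": 1.0},
                        censor_quantile=0.0, ig_panel={}, n_genes=0, n_concordant=0,
                        batch_effects={"A": (0.0, 1.0), "B": (1.0, 1.5)}, **kw)
        m, _, meta, truth = generate_cohort(cfg)
        return m, meta

    def test_single_batch_identity(self):
        cfg = SimConfig(seed=1, n_proteins=20, n_participants=6, followup_split=(2, 2, 2),
                        batch_effects={"only": (0.0, 1.0)}, ig_panel={},
                        n_genes=0, n_concordant=0)
        m, _, meta, _ = generate_cohort(cfg)
        out, model = correct_batch(m, meta)
        assert out.lfq.equals(m.lfq)
        assert (model.gamma.to_numpy() == 0).all()
        assert (model.delta_sq.to_numpy() == 1).all()

    def test_injected_shift_and_scale_removed(self):
        m, meta = self._cohort()
        out, _ = correct_batch(m, meta)
        b = meta.set_index("sample_id").loc[m.samples, "batch"].to_numpy()
        Y = out.lfq.to_numpy()
        systematic = (Y[:, b == "B"].mean(1) - Y[:, b == "A"].mean(1)).mean()
        assert abs(systematic) < 0.05
        vr = Y[:, b == "B"].var(1, ddof=1) / Y[:, b == "A"].var(1, ddof=1)
        assert 0.9 < np.median(vr) < 1.1

    def test_grand_mean_preserved(self):
        m, meta = self._cohort()
        out, _ = correct_batch(m, meta)
        gm_in = np.nanmean(m.lfq.to_numpy(), axis=1)
        gm_out = np.nanmean(out.lfq.to_numpy(), axis=1)
        assert np.abs(gm_in - gm_out).max() < 1e-6

    def test_noninformative_limit_matches_standardization_oracle(self):
        """With EB shrinkage off, the adjustment equals direct per-batch
        z-scoring rescaled to the pooled variance."""
        m, meta = self._cohort()
        out, _ = correct_batch(m, meta, covariates=(), shrink=False,
                               preserve_grand_mean=False)
        Y = m.lfq.to_numpy()
        b = meta.set_index("sample_id").loc[m.samples, "batch"].to_numpy()
        nA, nB = (b == "A").sum(), (b == "B").sum()
        mA, mB = Y[:, b == "A"].mean(1), Y[:, b == "B"].mean(1)
        sA = Y[:, b == "A"].std(1, ddof=1)
        sB = Y[:, b == "B"].std(1, ddof=1)
        grand = (nA * mA + nB * mB) / (nA + nB)
        resid = Y - np.where(b == "A", mA[:, None], mB[:, None])
        pooled = (resid**2).sum(1) / (nA + nB)
        Z = resid / np.where(b == "A", sA[:, None], sB[:, None])
        oracle = Z * np.sqrt(pooled)[:, None] + grand[:, None]
        assert np.abs(out.lfq.to_numpy() - oracle).max() < 1e-6

    def test_missing_entries_stay_missing(self):
        cfg = SimConfig(seed=12, n_proteins=100,
                        batch_effects={"A": (0.0, 1.0), "B": (0.6, 1.2)})
        m, _, meta, _ = generate_cohort(cfg)
        out, _ = correct_batch(m, meta)
        assert (out.lfq.isna() == m.lfq.isna()).all().all()

    def test_confounded_batch_raises(self):
        # batch identical to sex -> aliased covariate column
        meta = make_paired_meta((4, 0, 0))
        meta["batch"] = np.where(meta["sex"] == "F", "A", "B")
        m = make_matrix(np.random.default_rng(0).normal(20, 1, (30, len(meta))),
                        sample_ids=meta["sample_id"].tolist())
        with pytest.raises(DesignError, match="confounded"):
            correct_batch(m, meta, covariates=("sex",))

    def test_agrees_with_reference_combat(self, tmp_path):
        """Cross-check against the R reference EB implementation on
        complete data (covariate-protected, parametric priors)."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; reference cross-check cannot run")
        m, meta = self._cohort(seed=100)
        mine, _ = correct_batch(m, meta, covariates=("dol", "sex"),
                                preserve_grand_mean=False)
        m.lfq.to_csv(tmp_path / "mat.tsv", sep="\t")
        meta.to_csv(tmp_path / "meta.csv", index=False)
        script = textwrap.dedent("""
            suppressMessages(library(sva))
            args <- commandArgs(trailingOnly=TRUE)
            mat <- as.matrix(read.delim(args[1], row.names=1, check.names=FALSE))
            meta <- read.csv(args[2])
            meta <- meta[match(colnames(mat), meta$sample_id),]
            mod <- model.matrix(~factor(dol)+factor(sex), data=meta)
            out <- ComBat(dat=mat, batch=factor(meta$batch), mod=mod, par.prior=TRUE)
            write.table(out, args[3], sep="\\t", quote=FALSE)
        """)
        (tmp_path / "combat.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "combat.R"), str(tmp_path / "mat.tsv"),
             str(tmp_path / "meta.csv"), str(tmp_path / "ref.tsv")],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t", index_col=0)
        assert np.abs(mine.lfq.to_numpy() - ref.to_numpy()).max() < 1e-4


class TestGlobalDistributions:
    def test_identical_samples_give_zero_statistic_p_one(self):
        meta = make_paired_meta((2, 2, 2))
        m = make_matrix(np.tile(np.linspace(18, 30, 40)[:, None], (1, len(meta))),
                        sample_ids=meta["sample_id"].tolist())
        res = global_distribution_test(m, meta, n_perm=99, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_strong_shift_detected(self):
        cfg = SimConfig(seed=1, n_proteins=80, n_participants=9, followup_split=(3, 3, 3),
                        trajectory_classes={"flat": 1.0}, batch_effects={"b": (0.0, 1.0)},
                        ig_panel={}, n_genes=0, n_concordant=0)
        m, _, meta, _ = generate_cohort(cfg)
        shifted = m.copy()
        cols = meta.loc[meta.dol == 7, "sample_id"]
        shifted.lfq[cols] = shifted.lfq[cols] + 3.0
        res = global_distribution_test(shifted, meta, n_perm=1000, seed=0)
        assert res.p_value <= 0.01

    def test_single_sample_group_rejected(self):
        meta = make_paired_meta((1, 2, 2))
        m = make_matrix(np.random.default_rng(0).normal(20, 1, (30, len(meta))),
                        sample_ids=meta["sample_id"].tolist())
        with pytest.raises(DesignError, match="single"):
            global_distribution_test(m, meta, n_perm=10)
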