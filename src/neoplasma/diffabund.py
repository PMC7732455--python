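"""Paired differential abundance per follow-up day.

Each follow-up day (DOL 1, 3 or 7) defines an arm: the participants whose
second sample falls on that day, contributing their birth (DOL0) sample and
the follow-up sample.  Per protein, intensity is modelled as

    log2(LFQ) ~ 1 + day + sex + batch + (1 | participant)

and the day effect is tested by a 1-df likelihood-ratio test against the
identical model without the day term, both refit by maximum likelihood.
The day coefficient is the reported log2 fold change.  Remaining missing
values are simply omitted (no imputation at this stage).  Multiple-testing
correction is Benjamini-Hochberg within each follow-up day, and the
significance call is a dual gate: q < 0.05 and |log2FC| > 0.2.

Because the strict valid-value filter would silently discard proteins that
are detected on one day only, a complementary missingness analysis runs
Fisher's exact test on the detection/non-detection 2x2 table per protein on
the *pre-filter* matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FOLLOWUP_DOLS, DesignError, ProteinQuantMatrix
from .lmm import fit_random_intercept_batch, lrt_fixed_effect

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.05
DEFAULT_LFC = 0.2


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are passed through and excluded from the family size m.
    """
    p = np.asarray(p_values, float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _arm_samples(meta: pd.DataFrame, dol: int) -> pd.DataFrame:
    """Metadata rows for the DOL0 + DOLx samples of the participants whose
    follow-up day is ``dol``, ordered participant-major."""
    if dol not in FOLLOWUP_DOLS:
        raise ValueError(f"dol must be one of {FOLLOWUP_DOLS}, got {dol}")
    followup = meta[meta["dol"] == dol]
    if followup.empty:
        raise DesignError(f"no samples at DOL{dol}")
    pids = set(followup["participant_id"])
    arm = meta[(meta["participant_id"].isin(pids)) & (meta["dol"].isin([0, dol]))]
    return arm.sort_values(["participant_id", "dol"]).reset_index(drop=True)


def _build_design(arm: pd.DataFrame, dol: int, covariates) -> tuple[np.ndarray, list[str]]:
    """Intercept + day indicator + covariate dummies, dropping columns that
    are aliased with what is already in the design."""
    n = len(arm)
    cols: list[np.ndarray] = [np.ones(n), (arm["dol"] == dol).to_numpy(float)]
    names = ["intercept", f"dol{dol}"]
    for cov in covariates:
        if cov not in arm.columns:
            raise ValueError(f"unknown covariate {cov!r}")
        dummies = pd.get_dummies(arm[cov].astype(str), prefix=cov, drop_first=True)
        for cname in dummies.columns:
            cand = dummies[cname].to_numpy(float)
            X_try = np.column_stack(cols + [cand])
            if np.linalg.matrix_rank(X_try) > len(cols):
                cols.append(cand)
                names.append(cname)
            else:
                logger.warning(
                    "dropping covariate column %s (aliased with design) in DOL%d arm",
                    cname,
                    dol,
                )
    return np.column_stack(cols), names


def _paired_differences(lfq: pd.DataFrame, arm: pd.DataFrame, dol: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein mean within-participant (DOLx - DOL0) difference over
    complete pairs, plus the count of complete pairs."""
    base = arm[arm["dol"] == 0].set_index("participant_id")["sample_id"]
    foll = arm[arm["dol"] == dol].set_index("participant_id")["sample_id"]
    pids = base.index.intersection(foll.index)
    d = lfq[foll.loc[pids].to_numpy()].to_numpy() - lfq[base.loc[pids].to_numpy()].to_numpy()
    n_pairs = (~np.isnan(d)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_d = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=1)
    mean_d[n_pairs == 0] = np.nan
    return mean_d, n_pairs


class DifferentialResults:
    """Results container for one follow-up-day arm.

    ``frame`` columns: protein, gene, dol, log2fc, se, paired_mean_diff,
    p_lrt, q_value, significant, n_pairs, n_obs, sigma2_u, sigma2_e,
    not_testable.
    """

    def __init__(self, frame: pd.DataFrame, dol: int, fdr: float, lfc: float,
                 design_names: list[str]):
        self.frame = frame
        self.dol = dol
        self.fdr = fdr
        self.lfc = lfc
        self.design_names = design_names

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    @property
    def n_significant(self) -> int:
        return int(self.frame["significant"].sum())

    def summary(self) -> str:
        f = self.frame
        up = int((f["significant"] & (f["log2fc"] > 0)).sum())
        dn = int((f["significant"] & (f["log2fc"] < 0)).sum())
        return "\n".join(
            [
                f"Paired differential abundance, DOL{self.dol} vs DOL0",
                f"design: {' + '.join(self.design_names)} + (1|participant)",
                f"proteins tested: {int((~f['not_testable']).sum())} of {len(f)}",
                f"significant (q<{self.fdr:g}, |log2FC|>{self.lfc:g}): "
                f"{self.n_significant}  (up {up}, down {dn})",
            ]
        )


class PairedDifferentialModel:
    """Mixed-model differential abundance for one follow-up-day arm.

    Parameters
    ----------
    matrix : ProteinQuantMatrix
        log2 LFQ matrix, flag-filtered and valid-value-filtered for this
        arm; must not contain imputed values.
    meta : pd.DataFrame
        Validated sample metadata.
    dol : int
        Follow-up day (1, 3 or 7).
    covariates : sequence of str
        Metadata columns entering as fixed-effect nuisance terms.
    """

    def __init__(self, matrix: ProteinQuantMatrix, meta: pd.DataFrame, dol: int,
                 covariates=("sex", "batch")):
        if matrix.imputed:
            raise ValueError("differential testing must use the unimputed matrix")
        self.matrix = matrix
        self.meta = meta
        self.dol = int(dol)
        self.covariates = tuple(covariates)
        self.arm = _arm_samples(meta, self.dol)
        if self.arm["participant_id"].nunique() < 3:
            raise DesignError(f"DOL{dol} arm has fewer than 3 participants")
        self.exog, self.design_names = _build_design(self.arm, self.dol, self.covariates)

    def fit(self, fdr: float = DEFAULT_FDR, lfc: float = DEFAULT_LFC) -> DifferentialResults:
        lfq = self.matrix.lfq[self.arm["sample_id"].to_numpy()]
        Y = lfq.to_numpy(float)
        groups = self.arm["participant_id"].to_numpy()
        X_full = self.exog
        X_null = np.delete(X_full, 1, axis=1)  # drop the day indicator

        full_ml, p_lrt = lrt_fixed_effect(Y, X_full, X_null, groups)
        reml = fit_random_intercept_batch(Y, X_full, groups, reml=True)
        paired_mean, n_pairs = _paired_differences(self.matrix.lfq, self.arm, self.dol)

        not_testable = (n_pairs < 2) | ~full_ml.ok
        p = np.where(not_testable, np.nan, p_lrt)
        q = adjust_bh(p)
        log2fc = np.where(not_testable, np.nan, full_ml.beta[:, 1])

        frame = pd.DataFrame(
            {
                "protein": self.matrix.records["protein_group_id"].to_numpy(),
                "gene": self.matrix.records["gene_name"].to_numpy(),
                "dol": self.dol,
                "log2fc": log2fc,
                "se": full_ml.bse[:, 1],
                "paired_mean_diff": paired_mean,
                "p_lrt": p,
                "q_value": q,
                "significant": False,
                "n_pairs": n_pairs,
                "n_obs": full_ml.n_obs,
                "sigma2_u": reml.sigma2_u,
                "sigma2_e": reml.sigma2_e,
                "not_testable": not_testable,
            }
        )
        result = DifferentialResults(frame, self.dol, fdr, lfc, self.design_names)
        return call_significance(result, fdr=fdr, lfc=lfc)


def fit_paired_lmm(matrix: ProteinQuantMatrix, meta: pd.DataFrame, dol: int,
                   covariates=("sex", "batch"), fdr: float = DEFAULT_FDR,
                   lfc: float = DEFAULT_LFC) -> DifferentialResults:
    """One-call wrapper: build the arm model and fit it."""
    return PairedDifferentialModel(matrix, meta, dol, covariates).fit(fdr=fdr, lfc=lfc)


def call_significance(result: DifferentialResults, fdr: float = DEFAULT_FDR,
                      lfc: float = DEFAULT_LFC) -> DifferentialResults:
    """Apply the dual significance gate: q < fdr AND |log2FC| > lfc."""
    f = result.frame
    with np.errstate(invalid="ignore"):
        sig = (f["q_value"].to_numpy() < fdr) & (np.abs(f["log2fc"].to_numpy()) > lfc)
    f["significant"] = np.where(np.isnan(f["q_value"].to_numpy()), False, sig)
    result.fdr = fdr
    result.lfc = lfc
    return result


@dataclass
class MissingnessResult:
    """Fisher's-exact detection analysis for one arm.

    ``frame`` columns: protein, gene, dol, det_dol0, undet_dol0, det_dolx,
    undet_dolx, p_fisher.
    """

    frame: pd.DataFrame
    dol: int

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()


def fisher_missingness(prefilter_matrix: ProteinQuantMatrix, meta: pd.DataFrame,
                       dol: int) -> MissingnessResult:
    """Two-sided Fisher's exact test on the per-protein detection 2x2 table
    (detected/undetected x DOL0/DOLx) for the given arm, computed on the
    matrix before valid-value filtering."""
    arm = _arm_samples(meta, dol)
    s0 = arm.loc[arm["dol"] == 0, "sample_id"].to_numpy()
    sx = arm.loc[arm["dol"] == dol, "sample_id"].to_numpy()
    lfq = prefilter_matrix.lfq
    det0 = (~lfq[s0].isna()).sum(axis=1).to_numpy()
    detx = (~lfq[sx].isna()).sum(axis=1).to_numpy()
    n0, nx = len(s0), len(sx)

    p = np.empty(len(det0))
    cache: dict[tuple[int, int], float] = {}
    for i, (a, b) in enumerate(zip(det0, detx)):
        key = (int(a), int(b))
        if key not in cache:
            table = [[a, n0 - a], [b, nx - b]]
            cache[key] = stats.fisher_exact(table, alternative="two-sided")[1]
        p[i] = cache[key]

    frame = pd.DataFrame(
        {
            "protein": prefilter_matrix.records["protein_group_id"].to_numpy(),
            "gene": prefilter_matrix.records["gene_name"].to_numpy(),
            "dol": dol,
            "det_dol0": det0,
            "undet_dol0": n0 - det0,
            "det_dolx": detx,
            "undet_dolx": nx - detx,
            "p_fisher": p,
        }
    )
    return MissingnessResult(frame=frame, dol=dol)
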