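"""Immunoglobulin subclass ratios, half-life estimation and projections.

IgG subclass abundances are compared through iBAQ values (intensity-based
absolute quantitation: summed peptide intensity over the number of
theoretically observable peptides), which support between-protein ratio
comparisons that relative LFQ intensities do not.  Ratios are normalised
to a reference subclass (IgG2 by default) within each sample so that
cohorts measured under different experimental designs remain comparable.

Maternally transferred antibodies decay by first order,
C(t) = C(0) * 2^(-t / t_half).  On the paired log2-change scale this is a
straight line through the origin, Delta(t) = -t / t_half, so the apparent
half-life is estimated by zero-intercept least squares of participant
level Delta on elapsed days; the confidence interval is a nonparametric
bootstrap over participants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProteinQuantMatrix
from .trajectories import TrajectoryMatrix, pearson_with_p

logger = logging.getLogger(__name__)

IG_GENES = ("IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHM", "JCHAIN")
IGG_SUBCLASSES = ("IGHG1", "IGHG2", "IGHG3", "IGHG4")


@dataclass
class IgPanel:
    """Per-sample iBAQ values and reference-normalised ratios."""

    ibaq: pd.DataFrame     # samples x Ig genes (linear scale)
    ratios: pd.DataFrame   # samples x Ig genes, ratio to the reference
    ref: str
    meta: pd.DataFrame | None = None

    def dol_summary(self) -> pd.DataFrame:
        if self.meta is None:
            raise ValueError("panel carries no metadata")
        dol = self.meta.set_index("sample_id").loc[self.ratios.index, "dol"]
        return self.ratios.groupby(dol).mean()

    def to_frame(self) -> pd.DataFrame:
        out = self.ratios.add_prefix("ratio_")
        out = pd.concat([self.ibaq.add_prefix("ibaq_"), out], axis=1)
        return out.reset_index(names="sample_id")


def _ig_rows(matrix: ProteinQuantMatrix, mapping: dict[str, str] | None) -> dict[str, str]:
    """gene -> protein row id, matching on gene_name unless overridden."""
    gene_to_row = {}
    by_gene = matrix.records.groupby("gene_name").groups
    for gene in IG_GENES:
        key = (mapping or {}).get(gene, gene)
        if key in matrix.records.index:
            gene_to_row[gene] = key
        elif key in by_gene:
            rows = list(by_gene[key])
            gene_to_row[gene] = rows[0]
    return gene_to_row


def compute_ig_ratios(matrix: ProteinQuantMatrix, meta: pd.DataFrame | None = None,
                      ref: str = "IGHG2",
                      mapping: dict[str, str] | None = None) -> IgPanel:
    """Per-sample iBAQ ratios of each Ig species to the reference subclass.

    Samples in which the reference is not quantified get undefined ratios
    (logged).  Requires all four IgG subclasses to carry iBAQ values.
    """
    if matrix.ibaq is None:
        raise ValueError("matrix has no iBAQ values")
    rows = _ig_rows(matrix, mapping)
    missing = [g for g in IGG_SUBCLASSES if g not in rows]
    if missing:
        raise KeyError(f"IgG subclass rows not found: {missing}")
    genes = [g for g in IG_GENES if g in rows]
    ibaq = pd.DataFrame(
        {g: matrix.ibaq.loc[rows[g]] for g in genes},
    )
    ibaq.index.name = "sample_id"
    ref_vals = ibaq[ref]
    n_noref = int(ref_vals.isna().sum())
    if n_noref:
        logger.warning("reference %s unquantified in %d samples; ratios undefined there",
                       ref, n_noref)
    ratios = ibaq.div(ref_vals, axis=0)
    return IgPanel(ibaq=ibaq, ratios=ratios, ref=ref, meta=meta)


def compare_ratios(newborn: IgPanel, adult_reference: IgPanel) -> pd.DataFrame:
    """Welch two-sample t-test per subclass ratio, newborn vs adult."""
    rows = []
    for gene in IGG_SUBCLASSES:
        if gene not in newborn.ratios.columns or gene not in adult_reference.ratios.columns:
            continue
        a = newborn.ratios[gene].dropna().to_numpy()
        b = adult_reference.ratios[gene].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"fewer than 2 ratio values for {gene}")
        if a.std() == 0 and b.std() == 0:
            # degenerate case, e.g. the reference subclass (all ratios 1)
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"subclass": gene, "mean_newborn": a.mean(), "mean_adult": b.mean(),
                     "t": float(t), "p": float(p), "n_newborn": len(a), "n_adult": len(b)})
    return pd.DataFrame(rows)


class HalfLifeResults:
    """Apparent half-life estimate with bootstrap confidence interval."""

    def __init__(self, slope: float, ci_slope: tuple[float, float] | None,
                 n_pairs: int, n_days: int, protein: str,
                 ci_level: float = 0.95):
        self.slope = slope  # log2 units per day
        self.protein = protein
        self.n_pairs = n_pairs
        self.n_days = n_days
        self.decaying = slope < 0
        self.t_half = (-1.0 / slope) if slope < 0 else np.inf
        self.single_day = n_days < 2
        self.ci_level = ci_level
        if ci_slope is None:
            self.t_half_ci = (np.nan, np.nan)
        else:
            lo_s, hi_s = ci_slope
            # slope is negative for decay: more negative slope => shorter t_half
            lo = (-1.0 / hi_s) if hi_s < 0 else np.inf
            hi = (-1.0 / lo_s) if lo_s < 0 else np.inf
            self.t_half_ci = (min(lo, hi), max(lo, hi))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "protein": self.protein,
                "slope_log2_per_day": self.slope,
                "t_half_days": self.t_half,
                "ci_low_days": self.t_half_ci[0],
                "ci_high_days": self.t_half_ci[1],
                "n_pairs": self.n_pairs,
                "n_distinct_days": self.n_days,
            }]
        )

    def summary(self) -> str:
        th = "inf" if np.isinf(self.t_half) else f"{self.t_half:.1f} d"
        ci = (
            f" [{self.t_half_ci[0]:.1f}, {self.t_half_ci[1]:.1f}] d"
            if np.isfinite(self.t_half_ci[0]) else ""
        )
        lines = [
            f"Apparent half-life of {self.protein}",
            f"slope: {self.slope:.5f} log2/day   t_half: {th}{ci}",
            f"paired changes used: {self.n_pairs} over {self.n_days} follow-up day(s)",
        ]
        if self.single_day:
            lines.append("warning: all changes at a single day; slope rests on the "
                         "zero-intercept constraint alone")
        if not self.decaying:
            lines.append("no net decay (slope >= 0): half-life undefined (+inf)")
        return "\n".join(lines)


class HalfLifeModel:
    """Zero-intercept decay fit on participant-level paired log2 changes.

    Delta(0) = 0 holds by construction of the paired change, so the model
    is Delta = k * t with k the log2 slope per day and t_half = -1/k.
    """

    def __init__(self, traj: TrajectoryMatrix, protein: str):
        if protein not in traj.delta.index:
            raise KeyError(f"protein {protein!r} not in trajectory matrix")
        delta = traj.delta.loc[protein].to_numpy(float)
        days = traj.days.astype(float)
        mask = ~np.isnan(delta)
        self.protein = protein
        self.delta = delta[mask]
        self.days = days[mask]
        if len(self.delta) < 3:
            raise ValueError("need at least 3 paired changes")
        self.n_days = len(np.unique(self.days))
        if self.n_days < 2:
            logger.warning(
                "all paired changes at a single follow-up day; the slope is "
                "identified only through the origin constraint"
            )

    @staticmethod
    def _slope(days: np.ndarray, delta: np.ndarray) -> float:
        return float(np.dot(days, delta) / np.dot(days, days))

    def fit(self, bootstrap_n: int = 2000, seed: int | None = None,
            ci_level: float = 0.95) -> HalfLifeResults:
        slope = self._slope(self.days, self.delta)
        ci = None
        if bootstrap_n and len(self.delta) >= 3:
            rng = np.random.default_rng(seed)
            n = len(self.delta)
            idx = rng.integers(0, n, size=(bootstrap_n, n))
            d, t = self.delta[idx], self.days[idx]
            denom = (t * t).sum(axis=1)
            good = denom > 0
            slopes = (t * d).sum(axis=1)[good] / denom[good]
            if len(slopes):
                alpha = (1.0 - ci_level) / 2.0
                ci = (float(np.quantile(slopes, alpha)),
                      float(np.quantile(slopes, 1.0 - alpha)))
        return HalfLifeResults(slope=slope, ci_slope=ci, n_pairs=len(self.delta),
                               n_days=self.n_days, protein=self.protein,
                               ci_level=ci_level)


def estimate_half_life(traj: TrajectoryMatrix, protein: str,
                       bootstrap_n: int = 2000,
                       seed: int | None = None) -> HalfLifeResults:
    """One-call wrapper around :class:`HalfLifeModel`."""
    return HalfLifeModel(traj, protein).fit(bootstrap_n=bootstrap_n, seed=seed)


def project_concentration(baseline_conc: float, fold_change) -> np.ndarray:
    """Project a plasma concentration (mg/dl) from a baseline and a linear
    fold change (scalar or interval)."""
    fold = np.atleast_1d(np.asarray(fold_change, float))
    if baseline_conc <= 0 or (fold <= 0).any():
        raise ValueError("baseline and fold change must be positive")
    out = baseline_conc * fold
    return float(out[0]) if out.size == 1 else out


def correlate_pair(traj: TrajectoryMatrix, protein_a: str, protein_b: str) -> tuple[float, float]:
    """Pearson R (exact t-transform p) between two proteins' paired changes."""
    for p in (protein_a, protein_b):
        if p not in traj.delta.index:
            raise KeyError(f"protein {p!r} not in trajectory matrix")
    r, p, n = pearson_with_p(
        traj.delta.loc[protein_a].to_numpy(float),
        traj.delta.loc[protein_b].to_numpy(float),
    )
    if n < 3:
        raise ValueError("fewer than 3 complete pairs")
    if np.isnan(r):
        logger.warning("degenerate (zero-variance) input; correlation undefined")
    return r, p


def synthetic_adult_panel(n_adults: int = 30, seed: int = 7,
                          ref: str = "IGHG2") -> IgPanel:
    """Synthetic adult reference panel (this repo ships no real adult data).

    iBAQ values follow the adult subclass ordering IgG1 > IgG2 > IgG3 >
    IgG4 with an IgG1:IgG2 ratio around 2, i.e. substantially lower than
    the newborn ratio produced by the cohort generator, mimicking the
    contrast between a published adult cohort and newborn samples.
    """
    rng = np.random.default_rng(seed)
    base = {"IGHG1": 2.0e9, "IGHG2": 1.0e9, "IGHG3": 2.0e8, "IGHG4": 1.2e8,
            "IGHM": 1.5e9, "JCHAIN": 6.0e8}
    samples = [f"ADULT{i + 1:03d}" for i in range(n_adults)]
    load = rng.normal(0.0, 0.4, size=n_adults)
    data = {
        g: b * 2.0 ** (load + rng.normal(0.0, 0.3, size=n_adults))
        for g, b in base.items()
    }
    ibaq = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))
    ratios = ibaq.div(ibaq[ref], axis=0)
    return IgPanel(ibaq=ibaq, ratios=ratios, ref=ref)
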