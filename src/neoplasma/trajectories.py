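"""Per-participant change-vs-birth trajectories and their correlations.

Because the design is paired, the natural unit of change is
Delta = log2(intensity at DOLx) - log2(intensity at the same participant's
DOL0), one column per follow-up sample.  The protein-protein Pearson
correlation of these changes groups proteins with shared trajectories
(e.g. an acute-phase cluster), and the single-target screen ranks all
proteins by their correlation with one protein of interest (the serum
amyloid A-1 analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .io import ProteinQuantMatrix, validate_sample_meta

logger = logging.getLogger(__name__)


@dataclass
class TrajectoryMatrix:
    """Proteins x follow-up samples matrix of paired log2 changes."""

    delta: pd.DataFrame      # index proteins, columns follow-up sample ids
    meta: pd.DataFrame       # metadata rows for the follow-up samples
    genes: pd.Series         # protein -> gene name

    @property
    def days(self) -> np.ndarray:
        return self.meta.set_index("sample_id").loc[self.delta.columns, "dol"].to_numpy()


def compute_changes(matrix: ProteinQuantMatrix, meta: pd.DataFrame) -> TrajectoryMatrix:
    """Delta per follow-up sample against its own participant's DOL0;
    missing wherever either endpoint is missing."""
    meta = validate_sample_meta(meta)
    base = meta[meta["dol"] == 0].set_index("participant_id")["sample_id"]
    follow = meta[meta["dol"] != 0]
    usable = follow[follow["participant_id"].isin(base.index)]
    skipped = set(follow["participant_id"]) - set(usable["participant_id"])
    if skipped:
        logger.warning("participants without DOL0 excluded: %s", sorted(skipped))
    cols = {}
    for _, row in usable.iterrows():
        b = matrix.lfq[base.loc[row["participant_id"]]]
        f = matrix.lfq[row["sample_id"]]
        cols[row["sample_id"]] = f - b
    delta = pd.DataFrame(cols, index=matrix.lfq.index)
    return TrajectoryMatrix(
        delta=delta,
        meta=usable.reset_index(drop=True),
        genes=matrix.records["gene_name"],
    )


@dataclass
class CorrelationMatrixResult:
    corr: pd.DataFrame
    leaf_order: list  # protein ids in dendrogram order


def correlation_matrix(traj: TrajectoryMatrix, min_pairs: int = 6) -> CorrelationMatrixResult:
    """Pairwise-complete Pearson correlation of trajectories with
    average-linkage clustering on distance 1 - R.

    Pairs with fewer than ``min_pairs`` complete observations are
    undefined (NaN) in the matrix and treated as distance 1 (R = 0) for
    clustering only.  Leaf order is deterministic (index order breaks
    ties).
    """
    corr = traj.delta.T.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    dist = 1.0 - corr.to_numpy(float)
    dist = np.where(np.isnan(dist), 1.0, dist)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    order = leaves_list(Z)
    ids = list(corr.index)
    return CorrelationMatrixResult(corr=corr, leaf_order=[ids[i] for i in order])


@dataclass
class CorrelationScreen:
    """Per-protein correlation against one target protein's trajectory."""

    target: str
    frame: pd.DataFrame  # protein, gene, r, p, n_pairs (p < alpha only), sorted by R desc
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pairwise-complete Pearson R with the exact t-transform two-sided p."""
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        return np.nan, np.nan, n
    xv, yv = x[mask], y[mask]
    if xv.std() == 0 or yv.std() == 0:
        return np.nan, np.nan, n
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p), n


def screen_against(traj: TrajectoryMatrix, target_protein: str,
                   alpha: float = 0.05, min_pairs: int = 3) -> CorrelationScreen:
    """Correlate every protein's trajectory with the target protein's and
    retain raw p < alpha (no multiple-testing correction: the screen
    mirrors a raw-p exploratory table), sorted by R descending."""
    if target_protein not in traj.delta.index:
        raise KeyError(f"target protein {target_protein!r} not in trajectory matrix")
    t = traj.delta.loc[target_protein].to_numpy(float)
    rows = []
    for pid in traj.delta.index:
        r, p, n = pearson_with_p(traj.delta.loc[pid].to_numpy(float), t)
        if np.isnan(r) or n < min_pairs:
            continue
        rows.append({"protein": pid, "gene": traj.genes.get(pid, ""),
                     "r": r, "p": p, "n_pairs": n})
    frame = pd.DataFrame(rows)
    frame = frame[frame["p"] < alpha].sort_values("r", ascending=False).reset_index(drop=True)
    return CorrelationScreen(target=target_protein, frame=frame, alpha=alpha)
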