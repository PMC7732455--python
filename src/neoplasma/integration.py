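"""Protein-mRNA concordance of paired changes.

Whole-blood transcript levels need not track plasma protein levels (most
plasma proteins are liver-derived), so concordance is assessed on the
change-vs-DOL0 scale at two levels: across individual follow-up samples
and across the three per-DOL mean changes.  A gene-protein pair is called
concordant when the DOL-average correlation exceeds the threshold (0.3 by
default).  The three-point average-level correlation is intrinsically
unstable; results carry an explicit caveat column instead of a p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RnaCountMatrix, ProteinQuantMatrix, RECORD_COLUMNS
from .trajectories import TrajectoryMatrix, compute_changes, pearson_with_p

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.3


def normalize_counts(rna: RnaCountMatrix) -> pd.DataFrame:
    """Median-of-ratios size factors, then log2(count / size_factor + 1).

    Size factors are the per-sample median ratio to the per-gene geometric
    mean, computed over genes with all-positive counts.
    """
    counts = rna.counts.to_numpy(float)
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("sample(s) with all-zero counts")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    logc = np.log(counts[positive])
    log_geo = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_geo, axis=0))
    norm = np.log2(counts / sf[None, :] + 1.0)
    return pd.DataFrame(norm, index=rna.counts.index, columns=rna.counts.columns)


def rna_changes(normalized: pd.DataFrame, meta: pd.DataFrame) -> TrajectoryMatrix:
    """Gene-level paired change-vs-DOL0 matrix, mirroring the protein one."""
    shell = ProteinQuantMatrix(
        records=pd.DataFrame(
            {
                "protein_group_id": normalized.index,
                "gene_name": normalized.index,
                "is_reverse": False,
                "is_contaminant": False,
                "only_modified_site": False,
                "unique_peptides": 0,
            },
            index=pd.Index(normalized.index, name="protein_group_id"),
        )[RECORD_COLUMNS],
        lfq=normalized.copy(),
    )
    sub = meta[meta["sample_id"].isin(normalized.columns)].reset_index(drop=True)
    return compute_changes(shell, sub)


@dataclass
class ConcordanceResult:
    frame: pd.DataFrame
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    @property
    def n_concordant(self) -> int:
        return int(self.frame["concordant"].sum())


def concordance(
    protein_traj: TrajectoryMatrix,
    rna_traj: TrajectoryMatrix,
    pairs: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> ConcordanceResult:
    """Correlate paired protein and mRNA changes for each mapped pair.

    ``pairs`` has columns ``gene`` (row in the RNA trajectory) and
    ``protein`` (row in the protein trajectory).  For each pair the
    individual-level Pearson R uses the follow-up samples present in both
    matrices; the DOL-average R uses the three per-day mean changes; the
    concordance call applies ``threshold`` to the DOL-average R.  Pairs
    with fewer than 3 shared samples are skipped with a warning.
    """
    shared = [s for s in protein_traj.delta.columns if s in set(rna_traj.delta.columns)]
    days = protein_traj.meta.set_index("sample_id").loc[shared, "dol"].to_numpy()
    rows = []
    for _, pair in pairs.iterrows():
        gene, prot = pair["gene"], pair["protein"]
        if gene not in rna_traj.delta.index or prot not in protein_traj.delta.index:
            logger.warning("pair (%s, %s) absent from trajectories; skipped", gene, prot)
            continue
        pd_delta = protein_traj.delta.loc[prot, shared].to_numpy(float)
        rd_delta = rna_traj.delta.loc[gene, shared].to_numpy(float)
        both = ~(np.isnan(pd_delta) | np.isnan(rd_delta))
        if both.sum() < 3:
            logger.warning("pair (%s, %s) has <3 shared samples; skipped", gene, prot)
            continue
        r_ind, p_ind, n = pearson_with_p(pd_delta, rd_delta)

        day_means_p, day_means_r = [], []
        for d in sorted(set(days)):
            sel = both & (days == d)
            if sel.any():
                day_means_p.append(pd_delta[sel].mean())
                day_means_r.append(rd_delta[sel].mean())
        if len(day_means_p) >= 3:
            r_avg, _, _ = pearson_with_p(np.array(day_means_p), np.array(day_means_r))
        else:
            r_avg = np.nan
        rows.append(
            {
                "gene": gene,
                "protein": prot,
                "r_individual": r_ind,
                "p_individual": p_ind,
                "r_dol_average": r_avg,
                "concordant": bool(r_avg > threshold) if not np.isnan(r_avg) else False,
                "n_pairs": n,
                "caveat": "dol-average R uses n=3 points; unstable",
            }
        )
    return ConcordanceResult(frame=pd.DataFrame(rows), threshold=threshold)
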