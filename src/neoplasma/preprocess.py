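"""Filtering, batch correction and the global-distribution check.

Order of operations in the pipeline: flag filtering (contaminants, decoy
hits, modified-site-only identifications) first, then the valid-value
filter per comparison arm, then empirical-Bayes batch correction of the
log2 matrix.  The quantile-based permutation test checks whether whole
sample distributions differ between day-of-life groups, which would argue
against between-sample normalisation assumptions.

The batch correction is a parametric location/scale empirical-Bayes
adjustment (ComBat-style) written to tolerate missing entries: LFQ
missingness is MNAR and holes must neither be imputed nor break the EB
machinery, so every sum runs over observed entries only and missing
entries stay missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FOLLOWUP_DOLS, DesignError, ProteinQuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    n_input: int = 0
    n_removed_contaminant: int = 0
    n_removed_reverse: int = 0
    n_removed_modified_only: int = 0
    n_removed_valid_value: dict = field(default_factory=dict)  # per comparison dol
    n_quantifiable: int = 0

    def to_frame(self) -> pd.DataFrame:
        row = {
            "n_input": self.n_input,
            "n_removed_contaminant": self.n_removed_contaminant,
            "n_removed_reverse": self.n_removed_reverse,
            "n_removed_modified_only": self.n_removed_modified_only,
            "n_quantifiable": self.n_quantifiable,
        }
        for dol, n in sorted(self.n_removed_valid_value.items()):
            row[f"n_removed_valid_value_dol{dol}"] = n
        return pd.DataFrame([row])


def filter_flags(matrix: ProteinQuantMatrix) -> tuple[ProteinQuantMatrix, FilterReport]:
    """Remove contaminant, decoy (reverse) and modified-site-only rows.

    A row carrying several flags is counted once, with precedence
    contaminant > reverse > modified-site-only.
    """
    rec = matrix.records
    contaminant = rec["is_contaminant"].to_numpy(bool)
    reverse = rec["is_reverse"].to_numpy(bool) & ~contaminant
    modified = rec["only_modified_site"].to_numpy(bool) & ~contaminant & ~rec["is_reverse"].to_numpy(bool)
    drop = contaminant | reverse | modified
    report = FilterReport(
        n_input=len(rec),
        n_removed_contaminant=int(contaminant.sum()),
        n_removed_reverse=int(reverse.sum()),
        n_removed_modified_only=int(modified.sum()),
        n_quantifiable=int((~drop).sum()),
    )
    return matrix.subset_rows(~drop), report


def filter_valid_values(
    matrix: ProteinQuantMatrix,
    meta: pd.DataFrame,
    comparison_dol: int,
    min_fraction: float = 0.5,
) -> tuple[ProteinQuantMatrix, FilterReport]:
    """Keep proteins quantified in at least ``min_fraction`` of the DOL0
    samples AND of the follow-up-day samples of this comparison arm.

    "Quantifiable in less than 50%" of either group removes the protein;
    exactly 50% is kept.  Only participants belonging to the arm (those
    whose follow-up falls on ``comparison_dol``) are counted, matching the
    paired per-day testing.  No values are created or altered.
    """
    if comparison_dol not in FOLLOWUP_DOLS:
        raise ValueError(f"comparison_dol must be one of {FOLLOWUP_DOLS}")
    followup = meta[meta["dol"] == comparison_dol]
    if followup.empty:
        raise DesignError(f"empty comparison arm DOL{comparison_dol}")
    pids = set(followup["participant_id"])
    s0 = meta[(meta["participant_id"].isin(pids)) & (meta["dol"] == 0)]["sample_id"]
    sx = followup["sample_id"]

    obs0 = (~matrix.lfq[list(s0)].isna()).mean(axis=1).to_numpy()
    obsx = (~matrix.lfq[list(sx)].isna()).mean(axis=1).to_numpy()
    keep = (obs0 >= min_fraction) & (obsx >= min_fraction)
    report = FilterReport(
        n_input=matrix.n_proteins,
        n_removed_valid_value={comparison_dol: int((~keep).sum())},
        n_quantifiable=int(keep.sum()),
    )
    return matrix.subset_rows(keep), report


def filter_valid_values_union(
    matrix: ProteinQuantMatrix,
    meta: pd.DataFrame,
    min_fraction: float = 0.5,
) -> tuple[ProteinQuantMatrix, FilterReport]:
    """Union filter across all three arms (used before the global PCA):
    keep a protein if it passes the valid-value rule in at least one arm."""
    keep = np.zeros(matrix.n_proteins, bool)
    for dol in FOLLOWUP_DOLS:
        if (meta["dol"] == dol).any():
            kept, _ = filter_valid_values(matrix, meta, dol, min_fraction)
            keep |= matrix.records.index.isin(kept.records.index)
    report = FilterReport(
        n_input=matrix.n_proteins,
        n_removed_valid_value={"union": int((~keep).sum())},
        n_quantifiable=int(keep.sum()),
    )
    return matrix.subset_rows(keep), report


@dataclass
class BatchModel:
    """Estimated batch effects: per-protein location gamma (log2) and scale
    delta^2 per batch, after EB shrinkage, plus the prior hyperparameters."""

    batches: list
    gamma: pd.DataFrame      # proteins x batches
    delta_sq: pd.DataFrame   # proteins x batches
    priors: dict             # per batch: gamma_bar, tau_sq, a_prior, b_prior

    def to_frame(self) -> pd.DataFrame:
        g = self.gamma.add_prefix("gamma_")
        d = self.delta_sq.add_prefix("delta_sq_")
        out = pd.concat([g, d], axis=1).reset_index()
        return out


def _covariate_design(meta_aligned: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for cov in covariates:
        dummies = pd.get_dummies(meta_aligned[cov].astype(str), prefix=cov, drop_first=True)
        for cname in dummies.columns:
            cols.append(dummies[cname].to_numpy(float))
            names.append(cname)
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(meta_aligned), 0)), names


def correct_batch(
    matrix: ProteinQuantMatrix,
    meta: pd.DataFrame,
    covariates=("dol", "sex"),
    shrink: bool = True,
    preserve_grand_mean: bool = True,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[ProteinQuantMatrix, BatchModel]:
    """Empirical-Bayes location/scale batch adjustment on the log2 matrix.

    Per protein the data are standardised by an overall least-squares fit
    including the protected covariates, per-batch location (gamma) and
    scale (delta^2) are estimated, shrunk towards parametric priors
    (normal for gamma, inverse-gamma for delta^2) by iterated conditional
    modes, and removed.  Missing entries are excluded from every sum and
    remain missing.  With a single batch the input is returned unchanged
    (gamma = 0, delta^2 = 1 exactly).

    ``shrink=False`` disables the EB priors (direct per-batch
    standardisation); ``preserve_grand_mean`` recentres each protein to its
    original observed mean afterwards, a pure location shift absorbed by
    any downstream intercept.
    """
    meta_idx = meta.set_index("sample_id").loc[matrix.samples]
    batch_labels = meta_idx["batch"].astype(str)
    batches = sorted(batch_labels.unique())
    P = matrix.n_proteins
    if len(batches) == 1:
        model = BatchModel(
            batches=batches,
            gamma=pd.DataFrame(0.0, index=matrix.records.index, columns=batches),
            delta_sq=pd.DataFrame(1.0, index=matrix.records.index, columns=batches),
            priors={},
        )
        return matrix.copy(), model

    counts = batch_labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise DesignError(f"batches with fewer than 2 samples: {list(small.index)}")

    codes = np.array([batches.index(b) for b in batch_labels])
    B = len(batches)
    n = len(matrix.samples)
    Bmat = np.zeros((n, B))
    Bmat[np.arange(n), codes] = 1.0
    C, cov_names = _covariate_design(meta_idx.reset_index(), covariates)

    X = np.column_stack([Bmat, C])
    # confounding check: every covariate column must add rank beyond batch
    rank = np.linalg.matrix_rank(Bmat)
    aliased = []
    cur = Bmat
    for j, cname in enumerate(cov_names):
        cand = np.column_stack([cur, C[:, j]])
        if np.linalg.matrix_rank(cand) == rank:
            aliased.append(cname)
        else:
            cur, rank = cand, rank + 1
    if aliased:
        raise DesignError(
            f"batch is confounded with covariate column(s): {aliased}"
        )

    Y = matrix.lfq.to_numpy(float)
    obs = ~np.isnan(Y)
    n_obs = obs.sum(axis=1)

    # per-protein least squares on observed entries (designs differ by mask)
    beta = np.zeros((P, X.shape[1]))
    for p in range(P):
        m = obs[p]
        beta[p], *_ = np.linalg.lstsq(X[m], Y[p, m], rcond=None)

    weights = np.array([(codes == b).sum() for b in range(B)], float) / n
    alpha = beta[:, :B] @ weights                        # grand intercept
    cov_effect = beta[:, B:] @ C.T if C.shape[1] else np.zeros((P, n))
    stand_mean = alpha[:, None] + cov_effect
    fitted = beta @ X.T
    resid = np.where(obs, Y - fitted, 0.0)
    var_pooled = (resid**2).sum(axis=1) / np.maximum(n_obs, 1)
    var_pooled = np.maximum(var_pooled, 1e-12)

    Z = (Y - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_star = np.zeros((P, B))
    delta_star = np.ones((P, B))
    priors = {}
    for b, bname in enumerate(batches):
        in_b = codes == b
        Zb = Z[:, in_b]
        ob = obs[:, in_b]
        nb = ob.sum(axis=1).astype(float)
        sz = np.where(ob, Zb, 0.0).sum(axis=1)
        sz2 = np.where(ob, Zb**2, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            g_hat = sz / nb
            d_hat = (sz2 - nb * g_hat**2) / np.maximum(nb - 1, 1)
        g_hat = np.where(nb > 0, g_hat, 0.0)
        d_hat = np.where(nb > 1, np.maximum(d_hat, 1e-12), 1.0)

        if shrink:
            g_bar = float(np.mean(g_hat))
            tau_sq = float(np.var(g_hat, ddof=1)) if P > 1 else 1.0
            tau_sq = max(tau_sq, 1e-12)
            m_d = float(np.mean(d_hat))
            s2_d = float(np.var(d_hat, ddof=1)) if P > 1 else 1.0
            s2_d = max(s2_d, 1e-12)
            a_prior = (2 * s2_d + m_d**2) / s2_d
            b_prior = (m_d * s2_d + m_d**3) / s2_d
            priors[bname] = {
                "gamma_bar": g_bar, "tau_sq": tau_sq,
                "a_prior": a_prior, "b_prior": b_prior,
            }
            g_old, d_old = g_hat.copy(), d_hat.copy()
            for _ in range(max_iter):
                g_new = (nb * tau_sq * g_hat + d_old * g_bar) / (nb * tau_sq + d_old)
                sum2 = sz2 - 2 * g_new * sz + nb * g_new**2
                d_new = (b_prior + 0.5 * sum2) / (nb / 2 + a_prior - 1)
                change = max(
                    np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                    np.max(np.abs(d_new - d_old) / np.maximum(d_old, 1e-12)),
                )
                g_old, d_old = g_new, d_new
                if change < tol:
                    break
            gamma_star[:, b], delta_star[:, b] = g_old, d_old
        else:
            gamma_star[:, b], delta_star[:, b] = g_hat, d_hat

    Z_adj = (Z - gamma_star[:, codes]) / np.sqrt(delta_star[:, codes])
    Y_adj = Z_adj * np.sqrt(var_pooled)[:, None] + stand_mean
    Y_adj = np.where(obs, Y_adj, np.nan)

    if preserve_grand_mean:
        any_obs = obs.any(axis=1)
        shift = np.zeros(P)
        if any_obs.any():
            shift[any_obs] = (
                np.nanmean(Y[any_obs], axis=1) - np.nanmean(Y_adj[any_obs], axis=1)
            )
        Y_adj = Y_adj + shift[:, None]

    out = ProteinQuantMatrix(
        records=matrix.records.copy(),
        lfq=pd.DataFrame(Y_adj, index=matrix.lfq.index, columns=matrix.lfq.columns),
        ibaq=None if matrix.ibaq is None else matrix.ibaq.copy(),
        imputed=matrix.imputed,
    )
    model = BatchModel(
        batches=batches,
        gamma=pd.DataFrame(gamma_star, index=matrix.records.index, columns=batches),
        delta_sq=pd.DataFrame(delta_star, index=matrix.records.index, columns=batches),
        priors=priors,
    )
    return out, model


@dataclass
class GlobalDistributionTest:
    statistic: float
    p_value: float
    n_perm: int
    group: str


def test_global_distributions(
    matrix: ProteinQuantMatrix,
    meta: pd.DataFrame,
    group: str = "dol",
    n_probes: int = 100,
    n_perm: int = 10000,
    seed: int | None = None,
) -> GlobalDistributionTest:
    """Permutation test for global between-group differences in the sample
    intensity distributions (quantro-style).

    Each sample is summarised by ``n_probes`` equally spaced quantiles of
    its observed intensities; the statistic is the ratio of between-group
    to within-group mean squared deviation of these quantile vectors, and
    the p-value comes from permuting group labels with the add-one
    estimator p = (1 + #{permuted >= observed}) / (1 + n_perm).
    """
    meta_idx = meta.set_index("sample_id").loc[matrix.samples]
    labels = meta_idx[group].to_numpy()
    uniq, codes = np.unique(labels, return_inverse=True)
    G = len(uniq)
    if G < 2:
        raise DesignError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise DesignError(f"groups with a single sample: {uniq[sizes < 2]}")

    probs = np.linspace(0, 1, n_probes)
    Y = matrix.lfq.to_numpy(float)
    Q = np.nanquantile(Y, probs, axis=0)          # (n_probes, n_samples)
    if np.isnan(Q).any():
        raise ValueError("sample(s) without observed values")
    n = Q.shape[1]

    tss = float(((Q - Q.mean(axis=1, keepdims=True)) ** 2).sum())

    def _stat(code_vec: np.ndarray) -> float:
        onehot = np.zeros((n, G))
        onehot[np.arange(n), code_vec] = 1.0
        sums = Q @ onehot                          # (n_probes, G)
        means = sums / sizes
        grand = Q.mean(axis=1, keepdims=True)
        bss = float((sizes * ((means - grand) ** 2).sum(axis=0)).sum())
        # scale against the data magnitude so that exactly-identical samples
        # (tss and bss both pure roundoff) yield statistic 0, not 0/0 noise
        scale = float((Q**2).sum()) + 1e-30
        if bss <= 1e-12 * scale:
            return 0.0
        wss = max(tss - bss, 0.0)
        if wss <= 1e-12 * scale:
            return np.inf
        return (bss / (G - 1)) / (wss / (n - G))

    observed = _stat(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _stat(rng.permutation(codes)) >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return GlobalDistributionTest(statistic=observed, p_value=p, n_perm=n_perm, group=group)
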