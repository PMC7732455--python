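"""Left-censored imputation (PCA only) and principal component analysis.

Missing LFQ values are assumed left-censored: low-abundance proteins fail
detection.  For ordination only, missing entries are drawn from the lower
tail of each sample's fitted intensity distribution (a QRILC-style
truncated-normal draw with quantile cut-off ``q`` and width shrinkage
``tune_sigma``).  The imputed matrix is quarantined: it carries an
``imputed`` flag and every statistical stage refuses it, so imputation can
never leak into testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProteinQuantMatrix


@dataclass
class ImputationParams:
    """q: quantile of the fitted distribution truncating the draws from
    above (default 0.01); tune_sigma: shrink factor on the draw width
    (default 0.3); seed fixes the draws."""

    q: float = 0.01
    tune_sigma: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.tune_sigma <= 0:
            raise ValueError("tune_sigma must be positive")


def _censored_normal_fit(values: np.ndarray, n_total: int) -> tuple[float, float]:
    """Mean and sd of the complete per-sample distribution, estimated by
    regressing the observed order statistics on standard-normal quantiles.

    The observed values are treated as the upper ``n_obs`` order statistics
    of ``n_total`` draws, so the plotting positions account for the
    left-censored mass below the detection limit.
    """
    v = np.sort(values)
    n_obs = len(v)
    n_missing = n_total - n_obs
    ranks = n_missing + np.arange(1, n_obs + 1)
    p = (ranks - 0.375) / (n_total + 0.25)        # Blom plotting positions
    z = stats.norm.ppf(p)
    sigma, mu = np.polyfit(z, v, 1)
    return float(mu), float(abs(sigma))


def impute_left_censored(
    matrix: ProteinQuantMatrix, params: ImputationParams | None = None
) -> ProteinQuantMatrix:
    """Fill missing entries per sample with truncated-normal draws from the
    fitted distribution's lower tail; observed entries are untouched.

    The fitted complete distribution has censoring-aware mean/sd; draws use
    sd * tune_sigma and are truncated above at the distribution's
    ``q``-quantile, simulating signals from low-abundance proteins.
    Requires at least 10 observed values per sample.
    """
    params = params or ImputationParams()
    rng = np.random.default_rng(params.seed)
    lfq = matrix.lfq.copy()
    n_total = matrix.n_proteins

    for col in lfq.columns:
        vals = lfq[col].to_numpy(float)
        miss = np.isnan(vals)
        if not miss.any():
            continue
        obs = vals[~miss]
        if len(obs) < 10:
            raise ValueError(f"sample {col!r} has fewer than 10 observed values")
        mu, sigma = _censored_normal_fit(obs, n_total)
        upper = mu + sigma * stats.norm.ppf(params.q)
        width = sigma * params.tune_sigma
        b = (upper - mu) / width
        draws = stats.truncnorm.rvs(-np.inf, b, loc=mu, scale=width,
                                    size=int(miss.sum()), random_state=rng)
        vals[miss] = draws
        lfq[col] = vals

    return ProteinQuantMatrix(
        records=matrix.records.copy(),
        lfq=lfq,
        ibaq=None if matrix.ibaq is None else matrix.ibaq.copy(),
        imputed=True,
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame                  # samples x components
    loadings: pd.DataFrame                # proteins x components
    explained_variance_fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.reset_index(names="sample_id")
        return out


def run_pca(matrix: ProteinQuantMatrix, n_components: int = 10,
            scale: bool = False) -> PcaResult:
    """PCA of the complete (imputed) matrix via SVD.

    Proteins are mean-centred; unit-variance scaling is off by default
    because log2 LFQ intensities already share a scale.  Requires a
    complete matrix — impute first.
    """
    Y = matrix.lfq.to_numpy(float)
    if np.isnan(Y).any():
        raise ValueError(
            "matrix contains missing entries; run impute_left_censored first"
        )
    X = Y - Y.mean(axis=1, keepdims=True)
    if scale:
        sd = X.std(axis=1, ddof=1, keepdims=True)
        X = X / np.where(sd > 0, sd, 1.0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, len(s))
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (Vt[:n_components].T * s[:n_components]),
        index=pd.Index(matrix.samples, name="sample_id"),
        columns=comp_names,
    )
    loadings = pd.DataFrame(
        U[:, :n_components], index=matrix.lfq.index, columns=comp_names
    )
    return PcaResult(scores=scores, loadings=loadings,
                     explained_variance_fraction=frac[:n_components])
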