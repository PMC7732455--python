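"""Random-intercept linear mixed models, vectorised across proteins.

The differential-abundance stage fits, per protein, the model

    y_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, s2_u),  e_ij ~ N(0, s2_e)

where ``i`` indexes participants (clusters) and ``x`` carries the
day-of-life indicator and nuisance covariates.  Testing thousands of
proteins over hundreds of simulation replicates makes per-protein
general-purpose mixed-model fits prohibitively slow, so the likelihood is
profiled analytically here and maximised over the single variance ratio
``theta = s2_u / s2_e`` by a vectorised golden-section search: every
likelihood evaluation is a batch of small closed-form GLS solves.

Key identity: with V_i = I + theta * J (J the all-ones block for cluster
i), the inverse is V_i^{-1} = I - theta/(1 + n_i*theta) * J and
log|V_i| = log(1 + n_i*theta), so all cross-products reduce to cached
per-cluster sums.  Missing responses simply drop out of the sums, which is
how MNAR holes in the LFQ matrix are handled without imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class BatchLMMFit:
    """Per-protein estimates from :func:`fit_random_intercept_batch`.

    All arrays have length ``n_proteins`` along the first axis.
    """

    beta: np.ndarray        # (P, k) fixed-effect estimates
    bse: np.ndarray         # (P, k) standard errors (from the plug-in GLS covariance)
    sigma2_e: np.ndarray    # residual variance
    sigma2_u: np.ndarray    # participant (random intercept) variance
    llf: np.ndarray         # maximised log-likelihood (ML or REML)
    n_obs: np.ndarray       # observations used per protein
    ok: np.ndarray          # bool: fit well-defined (enough data, full rank)
    reml: bool = False


def _precompute(Y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> dict:
    P, n = Y.shape
    k = X.shape[1]
    M = (~np.isnan(Y)).astype(float)
    Yz = np.nan_to_num(Y)
    codes = np.unique(groups, return_inverse=True)[1]
    G = codes.max() + 1
    C = np.zeros((G, n))
    C[codes, np.arange(n)] = 1.0

    MX = M[:, :, None] * X[None, :, :]              # (P, n, k)
    return {
        "k": k,
        "XtX": np.einsum("pnj,nk->pjk", MX, X),
        "Xty": np.einsum("pnj,pn->pj", MX, Yz),
        "yty": (M * Yz**2).sum(axis=1),
        "S": np.einsum("gn,pnk->pgk", C, MX),       # cluster sums of x
        "T": np.einsum("gn,pn->pg", C, M * Yz),     # cluster sums of y
        "ncl": np.einsum("gn,pn->pg", C, M),        # cluster sizes
        "n_obs": M.sum(axis=1),
    }


def _profile_llf(theta: np.ndarray, pre: dict, reml: bool):
    """Profiled log-likelihood at per-protein theta; returns (llf, beta, A, sigma2)."""
    k = pre["k"]
    ncl, S, T = pre["ncl"], pre["S"], pre["T"]
    th = theta[:, None]
    w = th / (1.0 + ncl * th)                       # (P, G)
    A = pre["XtX"] - np.einsum("pg,pgj,pgk->pjk", w, S, S)
    b = pre["Xty"] - np.einsum("pg,pgj,pg->pj", w, S, T)
    q = pre["yty"] - (w * T**2).sum(axis=1)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    rss = np.maximum(q - (b * beta).sum(axis=1), 1e-300)
    logdet_v = np.log1p(ncl * th).sum(axis=1)
    n = pre["n_obs"]
    if reml:
        dof = np.maximum(n - k, 1.0)
        sigma2 = rss / dof
        _, logdet_a = np.linalg.slogdet(A)
        llf = -0.5 * (
            dof * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_v + logdet_a
        )
    else:
        sigma2 = rss / n
        llf = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_v)
    return llf, beta, A, sigma2


def fit_random_intercept_batch(
    Y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    reml: bool = False,
    theta_max: float = 100.0,
    n_golden: int = 45,
) -> BatchLMMFit:
    """Fit the random-intercept model to every row of ``Y`` at once.

    Parameters
    ----------
    Y : (P, n) array
        Responses; NaN marks a missing observation (dropped from that
        protein's fit).
    X : (n, k) array
        Shared fixed-effect design (full column rank on the observed rows
        of each usable protein).
    groups : (n,) array
        Cluster (participant) labels.
    reml : bool
        Maximise the REML criterion instead of ML.  Likelihood-ratio tests
        of fixed effects must use ``reml=False``.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    X = np.asarray(X, float)
    P, n = Y.shape
    k = X.shape[1]
    pre = _precompute(Y, X, groups)

    # fits are attempted only where the per-protein design has full rank
    with np.errstate(all="ignore"):
        eig = np.linalg.eigvalsh(pre["XtX"])
    ok = (pre["n_obs"] >= k + 1) & (eig[:, 0] > 1e-9 * np.maximum(eig[:, -1], 1e-30))
    if not ok.all():
        # freeze degenerate rows to an identity problem so batched solves succeed
        pre = dict(pre)
        bad = ~ok
        XtX = pre["XtX"].copy()
        XtX[bad] = np.eye(k)
        pre["XtX"] = XtX
        for key in ("Xty",):
            arr = pre[key].copy()
            arr[bad] = 0.0
            pre[key] = arr
        for key in ("S", "T"):
            arr = pre[key].copy()
            arr[bad] = 0.0
            pre[key] = arr
        yty = pre["yty"].copy()
        yty[bad] = 1.0
        pre["yty"] = yty
        nn = pre["n_obs"].copy()
        nn[bad] = k + 2
        pre["n_obs"] = nn

    lo = np.zeros(P)
    hi = np.full(P, float(theta_max))
    c = hi - _INVPHI * (hi - lo)
    d = lo + _INVPHI * (hi - lo)
    fc, *_ = _profile_llf(c, pre, reml)
    fd, *_ = _profile_llf(d, pre, reml)
    for _ in range(n_golden):
        left = fc >= fd
        hi = np.where(left, d, hi)
        lo = np.where(left, lo, c)
        c = hi - _INVPHI * (hi - lo)
        d = lo + _INVPHI * (hi - lo)
        fc, *_ = _profile_llf(c, pre, reml)
        fd, *_ = _profile_llf(d, pre, reml)
    theta = 0.5 * (lo + hi)
    llf, beta, A, sigma2 = _profile_llf(theta, pre, reml)
    # the boundary theta = 0 (no participant variance) is a frequent optimum
    llf0, beta0, A0, sigma20 = _profile_llf(np.zeros(P), pre, reml)
    at0 = llf0 >= llf
    llf = np.where(at0, llf0, llf)
    sigma2 = np.where(at0, sigma20, sigma2)
    theta = np.where(at0, 0.0, theta)
    beta = np.where(at0[:, None], beta0, beta)
    A = np.where(at0[:, None, None], A0, A)

    cov = sigma2[:, None, None] * np.linalg.inv(A)
    bse = np.sqrt(np.maximum(np.einsum("pjj->pj", cov), 0.0))

    nan = np.full(P, np.nan)
    return BatchLMMFit(
        beta=np.where(ok[:, None], beta, np.nan),
        bse=np.where(ok[:, None], bse, np.nan),
        sigma2_e=np.where(ok, sigma2, nan),
        sigma2_u=np.where(ok, theta * sigma2, nan),
        llf=np.where(ok, llf, nan),
        n_obs=np.where(ok, np.atleast_2d(~np.isnan(Y)).sum(axis=1), 0),
        ok=ok,
        reml=reml,
    )


def lrt_fixed_effect(
    Y: np.ndarray,
    X_full: np.ndarray,
    X_null: np.ndarray,
    groups: np.ndarray,
    **kwargs,
) -> tuple[BatchLMMFit, np.ndarray]:
    """Likelihood-ratio test of the columns present in ``X_full`` but not in
    ``X_null`` (1 df), both models refit by maximum likelihood.

    Returns the full-model ML fit and the per-protein chi-square p-values.
    """
    full = fit_random_intercept_batch(Y, X_full, groups, reml=False, **kwargs)
    null = fit_random_intercept_batch(Y, X_null, groups, reml=False, **kwargs)
    lr = np.maximum(2.0 * (full.llf - null.llf), 0.0)
    df = X_full.shape[1] - X_null.shape[1]
    p = stats.chi2.sf(lr, df)
    p = np.where(full.ok & null.ok, p, np.nan)
    return full, p


class RandomInterceptLMM:
    """Single-response convenience front-end, statsmodels-style.

    >>> model = RandomInterceptLMM(y, X, groups)
    >>> res = model.fit()
    >>> res.params, res.bse, res.sigma2_u
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, float)
        self.exog = np.asarray(exog, float)
        self.groups = np.asarray(groups)
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(self.exog.shape[1])
        ]

    def fit(self, reml: bool = False) -> "RandomInterceptLMMResults":
        fit = fit_random_intercept_batch(
            self.endog[None, :], self.exog, self.groups, reml=reml
        )
        return RandomInterceptLMMResults(self, fit)


class RandomInterceptLMMResults:
    def __init__(self, model: RandomInterceptLMM, fit: BatchLMMFit):
        self.model = model
        self.params = fit.beta[0]
        self.bse = fit.bse[0]
        self.sigma2_e = float(fit.sigma2_e[0])
        self.sigma2_u = float(fit.sigma2_u[0])
        self.llf = float(fit.llf[0])
        self.n_obs = int(fit.n_obs[0])
        self.converged = bool(fit.ok[0])
        self.reml = fit.reml

    def summary(self) -> str:
        lines = [
            "Random-intercept linear mixed model"
            + (" (REML)" if self.reml else " (ML)"),
            f"n_obs: {self.n_obs}   llf: {self.llf:.4f}",
            f"sigma2_e: {self.sigma2_e:.6g}   sigma2_u: {self.sigma2_u:.6g}",
            f"{'term':<16}{'coef':>12}{'se':>12}",
        ]
        for name, b, s in zip(self.model.exog_names, self.params, self.bse):
            lines.append(f"{name:<16}{b:>12.5f}{s:>12.5f}")
        return "\n".join(lines)
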