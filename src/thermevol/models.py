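"""Maximum-likelihood fitting of continuous-trait evolution models.

Four models are supported — Brownian motion (BM), single-optimum
Ornstein-Uhlenbeck (OU), Pagel's lambda (LA) and white noise (WN) — all
expressed as Gaussian models whose covariance is sigma^2 times a
model-specific transform of the phylogenetic shared-path matrix.  The
root state and sigma^2 are always profiled analytically (GLS closed
form); OU's alpha and LA's lambda are profiled by bounded 1-D
optimization.  ML throughout (divisor n); REML available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, optimize

from .errors import DegenerateTraitError, NumericalError, ParameterError
from .phylo import Phylogeny, PhyloCovariance, transform_covariance, vcv

__all__ = [
    "ModelFit", "MODELS", "bm_loglik", "gls_profile", "fit_model",
    "fit_all_models", "select_model", "align_trait", "chol_with_jitter",
]

MODELS = ("BM", "WN", "LA", "OU")
_MODEL_ORDER = {m: i for i, m in enumerate(MODELS)}
_N_PARAMS = {"BM": 2, "WN": 2, "LA": 3, "OU": 3}

#: relative diagonal jitter applied once if the Cholesky factorization fails
_JITTER = 1e-10


@dataclass
class ModelFit:
    """Fitted parameters of one model for one trait on one tree."""

    model: str
    sigma2: float            # trait-units^2 per unit branch length
    root_state: float        # GLS estimate of the root value
    lnL: float
    aic: float
    n_tips: int
    alpha: float | None = None     # OU only (1/My)
    lam: float | None = None       # LA only
    valid: bool = True             # False for degenerate (zero-variance) fits

    @property
    def k(self) -> int:
        return _N_PARAMS[self.model]


def chol_with_jitter(C: np.ndarray):
    """Cholesky factor of C, retrying once with a small diagonal jitter
    scaled by the tree height (max diagonal).  Raises NumericalError with a
    condition-number report if the jittered matrix still fails."""
    try:
        return linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError:
        pass
    scale = float(np.max(np.diag(C)))
    Cj = C + (_JITTER * scale) * np.eye(C.shape[0])
    try:
        return linalg.cho_factor(Cj, lower=True)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(C)
        raise NumericalError(
            f"covariance not positive definite after jitter "
            f"(condition number {cond:.3e})") from exc


def gls_profile(C: np.ndarray, x: np.ndarray):
    """Profile the mean and variance scale of a Gaussian model x ~ N(mu*1,
    sigma2*C).  Returns (mu_hat, Q, logdetC, cfac) where Q is the GLS
    quadratic form (x - mu*1)' C^-1 (x - mu*1)."""
    cfac = chol_with_jitter(C)
    one = np.ones_like(x)
    Ci1 = linalg.cho_solve(cfac, one)
    Cix = linalg.cho_solve(cfac, x)
    mu = float(one @ Cix) / float(one @ Ci1)
    r = x - mu
    Q = float(r @ linalg.cho_solve(cfac, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cfac[0]))))
    return mu, Q, logdet, cfac


def bm_loglik(C: PhyloCovariance | np.ndarray, x: Sequence[float],
              *, reml: bool = False):
    """Closed-form ML fit of x ~ N(mu*1, sigma2*C).

    Returns ``(lnL, sigma2_hat, root_hat)`` with the ML divisor n:
    ``lnL = -0.5 * (n*log(2*pi*sigma2) + log|C| + n)``.

    Raises :class:`DegenerateTraitError` when the GLS residual variance
    vanishes (constant trait).
    """
    Cm = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, float)
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ParameterError("need at least 2 species")
    if Cm.shape != (n, n):
        raise ParameterError(f"covariance is {Cm.shape}, trait has {n} entries")
    mu, Q, logdet, _ = gls_profile(Cm, x)
    scale = max(1.0, float(x @ x) / n)
    if Q <= n * 1e-25 * scale:
        raise DegenerateTraitError("trait has zero GLS variance (constant?)")
    if reml:
        sigma2 = Q / (n - 1)
        one = np.ones(n)
        cfac = chol_with_jitter(Cm)
        lognorm = math.log(float(one @ linalg.cho_solve(cfac, one)))
        lnL = -0.5 * ((n - 1) * math.log(2 * math.pi * sigma2)
                      + logdet + lognorm + (n - 1))
    else:
        sigma2 = Q / n
        lnL = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return lnL, sigma2, mu


def align_trait(tree: Phylogeny, x) -> np.ndarray:
    """Coerce a trait vector to the tree's tip-label order.

    Accepts a mapping/pandas Series keyed by species or a plain array
    already in tip order.
    """
    labels = tree.tip_labels
    if isinstance(x, Mapping) or hasattr(x, "reindex"):
        getter = x.get if isinstance(x, Mapping) else (lambda s: x[s])
        vals = []
        for s in labels:
            try:
                v = getter(s)
            except KeyError:
                v = None
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ParameterError(f"trait missing for species {s!r}")
            vals.append(float(v))
        return np.asarray(vals)
    arr = np.asarray(x, dtype=np.float64)
    if arr.size != len(labels):
        raise ParameterError(
            f"trait length {arr.size} != number of tips {len(labels)}")
    return arr


def _degenerate_fit(model: str, mu: float, n: int) -> ModelFit:
    return ModelFit(model=model, sigma2=0.0, root_state=mu, lnL=math.nan,
                    aic=math.nan, n_tips=n, valid=False)


def fit_model(tree: Phylogeny, x, model: str, *, reml: bool = False,
              aicc: bool = False) -> ModelFit:
    """Fit one evolution model by maximum likelihood.

    BM and WN are closed-form.  For LA and OU the single shape parameter
    is profiled by a grid scan plus bounded Brent refinement (tolerance
    1e-8 on the parameter); sigma^2 and the root state are solved
    analytically at every candidate.
    """
    model = model.upper()
    if model not in MODELS:
        raise ParameterError(f"unknown model {model!r}")
    xv = align_trait(tree, x)
    n = xv.size
    if model in ("OU", "LA") and n < 4:
        raise ParameterError(f"{model} needs >= 4 tips (3 free parameters)")
    cov = vcv(tree)
    # reorder covariance rows to the alignment order (tip-label order)
    T = tree.height
    k = _N_PARAMS[model]

    def finish(lnL, s2, mu, alpha=None, lam=None):
        aic = 2 * k - 2 * lnL
        if aicc:
            aic += 2 * k * (k + 1) / max(n - k - 1, 1)
        return ModelFit(model=model, sigma2=s2, root_state=mu, lnL=lnL,
                        aic=aic, n_tips=n, alpha=alpha, lam=lam)

    if np.allclose(xv, xv[0]):
        return _degenerate_fit(model, float(xv[0]), n)

    if model == "BM":
        lnL, s2, mu = bm_loglik(cov, xv, reml=reml)
        return finish(lnL, s2, mu)
    if model == "WN":
        Cw = transform_covariance(cov, "WN", tree_height=T)
        lnL, s2, mu = bm_loglik(Cw, xv, reml=reml)
        return finish(lnL, s2, mu)

    if model == "LA":
        def nll(lam):
            Ct = transform_covariance(cov, "LA", lam=float(lam))
            return -bm_loglik(Ct, xv, reml=reml)[0]
        lam_hat = _profile_1d(nll, np.linspace(0.0, 1.0, 21),
                              lo=0.0, hi=1.0, xatol=1e-8)
        Ct = transform_covariance(cov, "LA", lam=lam_hat)
        lnL, s2, mu = bm_loglik(Ct, xv, reml=reml)
        return finish(lnL, s2, mu, lam=lam_hat)

    # OU: profile alpha on a log grid spanning effectively-BM..effectively-WN
    ultra = tree.is_ultrametric()
    if not ultra:
        raise ParameterError("OU fitting requires an ultrametric tree")
    lo, hi = 1e-8 / T, 50.0 / T

    def nll_log(loga):
        Ct = transform_covariance(cov, "OU", alpha=math.exp(loga),
                                  tree_height=T)
        return -bm_loglik(Ct, xv, reml=reml)[0]

    loga_hat = _profile_1d(nll_log,
                           np.linspace(math.log(lo), math.log(hi), 30),
                           lo=math.log(lo), hi=math.log(hi), xatol=1e-10)
    alpha_hat = math.exp(loga_hat)
    Ct = transform_covariance(cov, "OU", alpha=alpha_hat, tree_height=T)
    lnL, s2, mu = bm_loglik(Ct, xv, reml=reml)
    return finish(lnL, s2, mu, alpha=alpha_hat)


def _profile_1d(nll, grid: np.ndarray, *, lo: float, hi: float,
                xatol: float) -> float:
    """Grid scan followed by bounded local refinement of a 1-D profile
    negative log-likelihood.  Returns the minimizer."""
    vals = np.asarray([nll(g) for g in grid])
    if not np.any(np.isfinite(vals)):
        raise NumericalError(
            f"profile likelihood non-finite on the entire grid: {list(grid)}")
    i = int(np.nanargmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    if a == b:
        return float(grid[i])
    res = optimize.minimize_scalar(
        nll, bounds=(max(a, lo), min(b, hi)), method="bounded",
        options={"xatol": xatol})
    best = float(res.x) if res.fun <= vals[i] else float(grid[i])
    return min(max(best, lo), hi)


def fit_all_models(tree: Phylogeny, x, *, reml: bool = False,
                   aicc: bool = False) -> list[ModelFit]:
    """Fit every model in :data:`MODELS` to the same data."""
    return [fit_model(tree, x, m, reml=reml, aicc=aicc) for m in MODELS]


def select_model(fits: Sequence[ModelFit]) -> ModelFit:
    """Lowest-AIC fit; ties broken by fewer parameters, then by the fixed
    order BM < WN < LA < OU."""
    fits = [f for f in fits]
    if not fits:
        raise ParameterError("select_model needs at least one fit")
    valid = [f for f in fits if f.valid]
    if not valid:
        return fits[0]
    return min(valid, key=lambda f: (f.aic, f.k, _MODEL_ORDER[f.model]))
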