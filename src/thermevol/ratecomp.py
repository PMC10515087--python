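"""Paired comparison of Brownian-motion evolutionary rates for two traits
measured on the same species, via a likelihood-ratio test of a common-rate
model against a separate-rates model.

Both models assume independent BM processes (between-trait evolutionary
correlation fixed at zero) with trait-specific root states; the constrained
model shares one sigma^2 across the two traits.  The LRT statistic
2*(lnL_separate - lnL_common) is referred to chi-square with 1 df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import linalg, stats

from .errors import ParameterError
from .models import ModelFit, bm_loglik, align_trait, gls_profile
from .phylo import Phylogeny, prune_to_taxa, vcv

__all__ = [
    "RateComparisonResult", "shared_species", "fit_separate_rates",
    "fit_common_rate", "lrt_rate_comparison", "compare_rates",
    "MIN_SHARED_SPECIES",
]

MIN_SHARED_SPECIES = 3


@dataclass
class RateComparisonResult:
    trait_A: str
    trait_B: str
    n_species: int
    sigma2_A: float
    sigma2_B: float
    lnL_separate: float
    lnL_common: float
    lrt: float
    df: int
    p_value: float
    faster_trait: str
    tree_height: float  # pruned-tree height, reported for auditability


def _clean(values: Mapping[str, float] | "object") -> dict[str, float]:
    if hasattr(values, "dropna") and hasattr(values, "to_dict"):  # Series
        values = values.dropna().to_dict()
    return {str(k): float(v) for k, v in dict(values).items()
            if v is not None and not (isinstance(v, float) and math.isnan(v))}


def shared_species(traits_a: Mapping[str, float], traits_b: Mapping[str, float],
                   tree: Phylogeny) -> list[str]:
    """Species with both trait values and a tip in the tree, sorted
    lexicographically.  Fewer than MIN_SHARED_SPECIES is an error."""
    a = set(_clean(traits_a))
    b = set(_clean(traits_b))
    common = sorted(a & b & set(tree.tip_labels))
    if len(common) < MIN_SHARED_SPECIES:
        raise ParameterError(
            f"rate comparison needs >= {MIN_SHARED_SPECIES} shared species "
            f"with tree tips, got {len(common)}")
    return common


def fit_separate_rates(tree: Phylogeny, x_a, x_b):
    """Two independent BM fits on the same (pruned) tree.

    Returns ``(fit_a, fit_b, lnL_separate)`` with
    ``lnL_separate = lnL_a + lnL_b``.
    """
    cov = vcv(tree)
    xa = align_trait(tree, x_a)
    xb = align_trait(tree, x_b)
    lnL_a, s2_a, mu_a = bm_loglik(cov, xa)
    lnL_b, s2_b, mu_b = bm_loglik(cov, xb)
    n = xa.size
    fit_a = ModelFit("BM", s2_a, mu_a, lnL_a, 4 - 2 * lnL_a, n)
    fit_b = ModelFit("BM", s2_b, mu_b, lnL_b, 4 - 2 * lnL_b, n)
    return fit_a, fit_b, lnL_a + lnL_b


def fit_common_rate(tree: Phylogeny, x_a, x_b):
    """ML under sigma2_A = sigma2_B = sigma2_c with separate means.

    sigma2_c = (Q_A + Q_B) / (2n) with Q the GLS quadratic forms;
    lnL_common = -0.5*(2n*log(2*pi*sigma2_c) + 2*log|C| + 2n).
    Returns ``(sigma2_c, lnL_common)``.
    """
    C = vcv(tree).matrix
    xa = align_trait(tree, x_a)
    xb = align_trait(tree, x_b)
    n = xa.size
    _, Qa, logdet, _ = gls_profile(C, xa)
    _, Qb, _, _ = gls_profile(C, xb)
    sigma2_c = (Qa + Qb) / (2 * n)
    if sigma2_c <= 0:
        raise ParameterError("both traits constant; common rate undefined")
    lnL = -0.5 * (2 * n * math.log(2 * math.pi * sigma2_c)
                  + 2 * logdet + 2 * n)
    return sigma2_c, lnL


def lrt_rate_comparison(tree: Phylogeny, x_a, x_b, *,
                        name_a: str = "A", name_b: str = "B"
                        ) -> RateComparisonResult:
    """Assemble the separate- and common-rate fits and the chi-square(1)
    likelihood-ratio test.  Traits must already be restricted to the tips
    of ``tree`` (see :func:`compare_rates` for the convenience wrapper)."""
    fit_a, fit_b, lnL_sep = fit_separate_rates(tree, x_a, x_b)
    _, lnL_com = fit_common_rate(tree, x_a, x_b)
    lrt = 2.0 * (lnL_sep - lnL_com)
    if lrt < -1e-8:
        raise ParameterError(f"nesting violated: LRT = {lrt}")
    lrt = max(lrt, 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    faster = name_a if fit_a.sigma2 >= fit_b.sigma2 else name_b
    return RateComparisonResult(
        trait_A=name_a, trait_B=name_b, n_species=fit_a.n_tips,
        sigma2_A=fit_a.sigma2, sigma2_B=fit_b.sigma2,
        lnL_separate=lnL_sep, lnL_common=lnL_com, lrt=lrt, df=1,
        p_value=p, faster_trait=faster, tree_height=tree.height)


def compare_rates(tree: Phylogeny, traits_a: Mapping[str, float],
                  traits_b: Mapping[str, float], *,
                  name_a: str = "A", name_b: str = "B"
                  ) -> RateComparisonResult:
    """Full paired comparison: intersect species, prune the tree, run the
    LRT.  ``traits_*`` are species-keyed mappings (NaN treated as missing)."""
    ta, tb = _clean(traits_a), _clean(traits_b)
    common = shared_species(ta, tb, tree)
    sub = prune_to_taxa(tree, common)
    xa = {s: ta[s] for s in common}
    xb = {s: tb[s] for s in common}
    return lrt_rate_comparison(sub, xa, xb, name_a=name_a, name_b=name_b)


def parametric_bootstrap_p(tree: Phylogeny, x_a, x_b, *, n_boot: int = 199,
                           seed: int = 0) -> float:
    """Optional small-n alternative to the chi-square reference: simulate
    the common-rate null on the same tree and return the bootstrap tail
    probability of the observed LRT."""
    from .simulate import simulate_bivariate_traits

    obs = lrt_rate_comparison(tree, x_a, x_b)
    s2c, _ = fit_common_rate(tree, x_a, x_b)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        za, zb = simulate_bivariate_traits(tree, s2c, s2c, 0.0, 0.0, 0.0, rng)
        rep = lrt_rate_comparison(tree, za, zb)
        exceed += rep.lrt >= obs.lrt
    return (1 + exceed) / (n_boot + 1)
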