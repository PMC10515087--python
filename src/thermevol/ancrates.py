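"""Ancestral state reconstruction on the best-model covariance structure,
per-tip absolute evolutionary rates, and the paired t-test on ln rates.

Ancestral estimates are GLS conditional means: with the tip covariance
transformed per the selected model, the estimate for internal node k is

    a_k = mu + c_k' C'^{-1} (x - mu 1)

where c_k holds node-to-tip covariances obtained by applying the same
transform rule to the shared root-ward path length of (k, tip).  The
absolute rate of a tip is |tip value - parent estimate| / terminal branch
length (trait units per My); under WN the "ancestor" is the grand mean and
the divisor is the tip depth (star structure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, stats

from .errors import ParameterError
from .models import ModelFit, align_trait, chol_with_jitter
from .phylo import Phylogeny, ou_covariance_value, transform_covariance, vcv

__all__ = [
    "TipRate", "PairedRateTest", "reconstruct_ancestors",
    "tip_absolute_rates", "paired_rate_test", "node_tip_shared_paths",
]


@dataclass
class TipRate:
    species: str
    trait: str
    tip_value: float
    ancestor_estimate: float
    branch_time: float       # My
    abs_rate: float          # trait units / My
    model_used: str


@dataclass
class PairedRateTest:
    trait_A: str
    trait_B: str
    m: int                   # pairs used
    mean_ln_rate_A: float
    mean_ln_rate_B: float
    t_statistic: float
    df: int
    p_value: float
    n_excluded_zero: int
    degenerate: bool = False  # zero-variance difference vector


def node_tip_shared_paths(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray]:
    """Shared root-ward path length between every internal node and every
    tip (in tip-label order).

    Returns ``(internal_ids, M)`` where ``M[r, i]`` is the depth of
    MRCA(internal_ids[r], tip i).  For a tip below the node that is the
    node's own depth; otherwise the depth of the deepest common ancestor.
    """
    depth = tree.depths()
    leaf_order = tree._leaf_order()
    tix = {v: i for i, v in enumerate(leaf_order)}
    n = len(leaf_order)

    tips_below: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        v = int(v)
        kids = tree.children(v)
        if not kids:
            tips_below[v] = np.asarray([tix[v]], dtype=np.int64)
        else:
            tips_below[v] = np.concatenate([tips_below[c] for c in kids])

    internal = [int(v) for v in tree.postorder() if tree.children(int(v))]
    M = np.empty((len(internal), n))
    for r, k in enumerate(internal):
        row = M[r]
        row[tips_below[k]] = depth[k]
        prev, a = k, int(tree.parent[k])
        while a >= 0:
            mask = np.ones(n, dtype=bool)
            mask[tips_below[prev]] = False
            idx = tips_below[a][mask[tips_below[a]]]
            row[idx] = depth[a]
            prev, a = a, int(tree.parent[a])
        # anything above the root's subtree cannot exist; all tips covered
    return np.asarray(internal, dtype=np.int64), M


def _transform_cross(M: np.ndarray, fit: ModelFit, T: float) -> np.ndarray:
    """Apply the fitted model's covariance rule to node-tip shared paths."""
    model = fit.model
    if model == "BM":
        return M
    if model == "LA":
        return fit.lam * M
    if model == "OU":
        return ou_covariance_value(M, fit.alpha, T)
    if model == "WN":
        return np.zeros_like(M)
    raise ParameterError(f"unknown model {model!r}")


def reconstruct_ancestors(tree: Phylogeny, x, best: ModelFit
                          ) -> dict[int, float]:
    """GLS conditional-mean ancestral states for every internal node.

    ``best`` must have been fitted on exactly this (tree, trait) pair; the
    root estimate equals the fitted root state.  Returns a node-id -> state
    map covering all internal nodes.
    """
    xv = align_trait(tree, x)
    if best.n_tips != xv.size:
        raise ParameterError(
            f"fit was for {best.n_tips} tips, tree has {xv.size}")
    cov = vcv(tree)
    T = tree.height
    kwargs = {"alpha": best.alpha, "lam": best.lam, "tree_height": T}
    Ct = transform_covariance(cov, best.model, **kwargs).matrix
    mu = best.root_state
    if not best.valid:  # constant trait: every ancestor equals it
        return {int(k): mu for k in tree.postorder() if tree.children(int(k))}
    cfac = chol_with_jitter(Ct)
    w = linalg.cho_solve(cfac, xv - mu)
    internal, M = node_tip_shared_paths(tree)
    cross = _transform_cross(M, best, T)
    est = mu + cross @ w
    out = {int(k): float(e) for k, e in zip(internal, est)}
    out[tree.root] = float(mu) if best.model == "WN" else out[tree.root]
    return out


def tip_absolute_rates(tree: Phylogeny, x, anc: Mapping[int, float], *,
                       trait: str = "trait", model_used: str = "BM",
                       time_mode: str = "terminal") -> list[TipRate]:
    """Per-tip absolute evolutionary rates.

    ``time_mode='terminal'`` (default) divides the ancestor-descendant
    difference by the terminal branch length; ``'depth'`` divides by the
    tip's root-to-tip age instead.  Under WN the ancestor is the grand
    mean and the divisor is always the tip depth.  Tips whose divisor is
    zero are excluded (callers count them via the returned list length).
    """
    if time_mode not in ("terminal", "depth"):
        raise ParameterError(f"unknown time_mode {time_mode!r}")
    xv = align_trait(tree, x)
    depth = tree.depths()
    leaf_order = tree._leaf_order()
    rates = []
    for i, v in enumerate(leaf_order):
        if model_used == "WN":
            a = anc[tree.root]
            dt = float(depth[v])
        else:
            p = int(tree.parent[v])
            if p not in anc:
                raise ParameterError(f"ancestor map missing parent of tip {v}")
            a = anc[p]
            dt = float(depth[v]) if time_mode == "depth" else float(tree.blen[v])
        if dt <= 0:
            continue
        val = float(xv[i])
        rates.append(TipRate(
            species=tree.labels[v], trait=trait, tip_value=val,
            ancestor_estimate=float(a), branch_time=dt,
            abs_rate=abs(val - a) / dt, model_used=model_used))
    return rates


def _rate_map(rates) -> dict[str, float]:
    if isinstance(rates, Mapping):
        return {str(k): float(v) for k, v in rates.items()}
    return {r.species: r.abs_rate for r in rates}


def paired_rate_test(rates_a, rates_b, *, name_a: str = "A",
                     name_b: str = "B") -> PairedRateTest:
    """Paired t-test on ln(abs_rate) differences over shared species.

    Species with a zero rate for either trait are excluded from the ln
    scale (count reported).  A zero-variance difference vector is handled
    explicitly: all-equal rates give t = 0, p = 1; a constant nonzero
    log-ratio is flagged degenerate with p = 0.
    """
    ra, rb = _rate_map(rates_a), _rate_map(rates_b)
    common = sorted(set(ra) & set(rb))
    usable = [s for s in common if ra[s] > 0 and rb[s] > 0]
    n_excluded = len(common) - len(usable)
    m = len(usable)
    if m < 3:
        raise ParameterError(
            f"paired test needs >= 3 usable pairs, got {m} "
            f"({n_excluded} excluded for zero rates)")
    la = np.log([ra[s] for s in usable])
    lb = np.log([rb[s] for s in usable])
    d = la - lb
    dbar = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(dbar)):
        if abs(dbar) <= 1e-12:
            t, p, degen = 0.0, 1.0, False
        else:
            t = math.copysign(math.inf, dbar)
            p, degen = 0.0, True
    else:
        t = dbar / (sd / math.sqrt(m))
        p = 2.0 * float(stats.t.sf(abs(t), df=m - 1))
        degen = False
    return PairedRateTest(
        trait_A=name_a, trait_B=name_b, m=m,
        mean_ln_rate_A=float(la.mean()), mean_ln_rate_B=float(lb.mean()),
        t_statistic=t, df=m - 1, p_value=p,
        n_excluded_zero=n_excluded, degenerate=degen)
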