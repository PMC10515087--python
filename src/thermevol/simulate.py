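"""Synthetic data with the statistical structure the analysis assumes:
Yule trees, correlated trait evolution under BM/OU/lambda, hardening
strata with distinct rate regimes, and occurrence clouds on smooth
climate-gradient grids.

Trait simulation draws from the exact multivariate normal implied by the
model covariance (Cholesky factorization), so OU/lambda structures share a
code path with the likelihood transforms; an independent branchwise BM
simulator is provided as a cross-check oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .phylo import Phylogeny, PhyloCovariance, transform_covariance, vcv, write_newick
from .niche import ClimateGrid

__all__ = [
    "ScenarioConfig", "ScenarioBundle", "simulate_yule_tree",
    "simulate_bivariate_traits", "simulate_ou_traits",
    "simulate_bm_branchwise", "make_paper_like_scenario", "write_scenario",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(n: int, birth_rate: float, seed) -> Phylogeny:
    """Pure-birth ultrametric tree conditioned on exactly ``n`` tips.

    Lineages split at exponential waiting times with total rate
    ``k * birth_rate``; a final waiting period at ``n`` lineages sets the
    present, making all tips equidistant from the root.
    """
    if n < 2:
        raise ParameterError("need n >= 2 tips")
    if not (birth_rate > 0):
        raise ParameterError("birth_rate must be > 0")
    rng = _as_rng(seed)

    parent = [-1]
    birth_time = [0.0]          # time the node came into existence
    active = [0]                # currently unsplit lineages
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        v = active.pop(i)
        for _ in range(2):
            parent.append(v)
            birth_time.append(t)
            active.append(len(parent) - 1)
    t += rng.exponential(1.0 / (n * birth_rate))

    parent = np.asarray(parent, dtype=np.int64)
    n_nodes = parent.size
    is_tip = np.ones(n_nodes, dtype=bool)
    is_tip[parent[parent >= 0]] = False
    end_time = np.where(is_tip, t, 0.0)
    # internal nodes end when their children are born
    for v in range(n_nodes):
        p = parent[v]
        if p >= 0:
            end_time[p] = birth_time[v]
    blen = end_time - np.asarray(birth_time)
    blen[0] = 0.0
    labels: list[str | None] = [None] * n_nodes
    c = 0
    for v in range(n_nodes):
        if is_tip[v]:
            c += 1
            labels[v] = f"sp{c:04d}"
    return Phylogeny(parent, blen, labels)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def _chol_of(tree_or_cov) -> tuple[list[str], np.ndarray]:
    cov = tree_or_cov if isinstance(tree_or_cov, PhyloCovariance) \
        else vcv(tree_or_cov)
    L = np.linalg.cholesky(cov.matrix)
    return list(cov.species), L


def simulate_bivariate_traits(tree, s2_a: float, s2_b: float, rho: float,
                              root_a: float, root_b: float, seed
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Correlated BM pair: the 2n-vector (A, B) is multivariate normal with
    covariance [[s2_a*C, rho*sqrt(s2_a*s2_b)*C], [., s2_b*C]].

    Returns two arrays in the tree's tip-label order.
    """
    if not (s2_a > 0 and s2_b > 0):
        raise ParameterError("sigma^2 must be > 0")
    if not (-1.0 <= rho <= 1.0):
        raise ParameterError("rho must lie in [-1, 1]")
    rng = _as_rng(seed)
    _, L = _chol_of(tree)
    n = L.shape[0]
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    a = root_a + np.sqrt(s2_a) * (L @ z1)
    b = root_b + np.sqrt(s2_b) * (L @ (rho * z1 + np.sqrt(1 - rho ** 2) * z2))
    return a, b


def simulate_ou_traits(tree, sigma2: float, alpha: float, optimum: float,
                       seed) -> np.ndarray:
    """Single-optimum, fixed-root OU draw (root at the optimum), using the
    same covariance transform as the likelihood code."""
    if not (alpha > 0):
        raise ParameterError("alpha must be > 0")
    if not (sigma2 > 0):
        raise ParameterError("sigma^2 must be > 0")
    rng = _as_rng(seed)
    cov = transform_covariance(vcv(tree), "OU", alpha=alpha)
    w = np.linalg.eigvalsh(cov.matrix)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ParameterError("requested OU covariance is not PSD")
    L = np.linalg.cholesky(cov.matrix + 1e-14 * np.eye(cov.matrix.shape[0]))
    return optimum + np.sqrt(sigma2) * (L @ rng.standard_normal(L.shape[0]))


def simulate_bm_branchwise(tree: Phylogeny, sigma2: float, root: float,
                           seed) -> np.ndarray:
    """Independent BM oracle: accumulate Gaussian increments branch by
    branch down the tree (no covariance factorization involved).  Returns
    tip values in tip-label order."""
    rng = _as_rng(seed)
    state = np.empty(tree.n_nodes)
    for v in tree.preorder():
        v = int(v)
        p = int(tree.parent[v])
        if p < 0:
            state[v] = root
        else:
            state[v] = state[p] + rng.standard_normal() * np.sqrt(
                sigma2 * tree.blen[v])
    leaf_order = tree._leaf_order()
    return state[leaf_order]


# ---------------------------------------------------------------------------
# End-to-end scenario
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Knobs for the end-to-end synthetic scenario.

    The default configuration emulates the structure the analysis targets:
    fast-evolving cold tolerance, a slower coupled cold niche (tightly
    coupled in the hardened stratum, weakly otherwise), and near-equal-rate
    heat tolerance / warm niche.
    """

    n_species: int = 200
    birth_rate: float = 1.0
    seed: int = 0
    # cold side
    s2_tmin: float = 40.0
    s2_tmin_nonhard: float = 1.0
    root_tmin: float = -10.0
    # warm side (near-equal rates)
    s2_tmax: float = 1.0
    s2_mtwm: float = 1.0
    root_tmax: float = 45.0
    root_mtwm: float = 33.0
    rho_warm: float = 0.3
    # trait -> niche coupling (MTCM = c + slope * T_min + BM noise)
    coupling_hardened: float = 0.2
    coupling_nonhard: float = 0.05
    s2_mtcm_noise_hardened: float = 0.5
    s2_mtcm_noise_nonhard: float = 2.0
    root_mtcm: float = 0.0
    # strata
    p_hardened: float = 0.5
    p_nonhard: float = 0.3
    p_unknown: float = 0.2
    group_probs: tuple = (0.7, 0.15, 0.15)   # angiosperm, gymnosperm, fern
    # measurements & occurrences
    n_measurements_max: int = 3
    measurement_sd: float = 0.25
    n_occurrences: int = 30
    occurrence_sd_deg: float = 0.4
    # climate grid: bio6 ramps with latitude, bio5 with longitude
    grid_shape: tuple = (120, 120)
    grid_cellsize: float = 0.5
    bio6_at_equator: float = 18.0  # kept below bio5_west so bio5 >= bio6 everywhere
    bio6_per_deg_lat: float = -0.8
    bio5_west: float = 20.0
    bio5_per_deg_lon: float = 0.4

    def validate(self) -> None:
        if self.n_species < 4:
            raise ParameterError("n_species must be >= 4")
        props = (self.p_hardened, self.p_nonhard, self.p_unknown)
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ParameterError("stratum proportions must sum to 1")
        for s2 in (self.s2_tmin, self.s2_tmax, self.s2_mtwm,
                   self.s2_mtcm_noise_hardened, self.s2_mtcm_noise_nonhard):
            if not (s2 > 0):
                raise ParameterError("all sigma^2 must be > 0")


@dataclass
class ScenarioBundle:
    tree: Phylogeny
    trait_rows: pd.DataFrame     # raw measurement rows
    occurrences: pd.DataFrame
    bio5_grid: ClimateGrid
    bio6_grid: ClimateGrid
    sites: pd.DataFrame          # experimental-site coordinates per species
    truth: dict = field(default_factory=dict)


def make_paper_like_scenario(config: ScenarioConfig | None = None
                             ) -> ScenarioBundle:
    """Generate the full input bundle (tree, raw trait rows, occurrences,
    climate grids, site table) from one seed."""
    cfg = config or ScenarioConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    tree = simulate_yule_tree(cfg.n_species, cfg.birth_rate, rng)
    species = tree.tip_labels
    n = len(species)

    # strata
    strata = rng.choice(["hardened", "non_hardened", "unknown"], size=n,
                        p=[cfg.p_hardened, cfg.p_nonhard, cfg.p_unknown])
    groups = rng.choice(["angiosperm", "gymnosperm", "fern"], size=n,
                        p=cfg.group_probs)

    # cold side: two T_min surfaces (fast for hardened/unknown, slow for
    # non-hardened), one noise surface per regime for the niche coupling
    # per-stratum rate regimes as scalings of shared BM surfaces: this keeps
    # phylogenetic correlation across strata (a patchwork of independent
    # surfaces would mimic an enormous rate at stratum boundaries) and makes
    # equal-rate configurations exactly BM for null calibration
    _, L = _chol_of(tree)
    z = lambda: rng.standard_normal(n)
    tmin_dev = L @ z()
    noise_dev = L @ z()
    hard = strata != "non_hardened"
    s2_t = np.where(hard, cfg.s2_tmin, cfg.s2_tmin_nonhard)
    s2_e = np.where(hard, cfg.s2_mtcm_noise_hardened, cfg.s2_mtcm_noise_nonhard)
    slope = np.where(hard, cfg.coupling_hardened, cfg.coupling_nonhard)
    tmin = cfg.root_tmin + np.sqrt(s2_t) * tmin_dev
    mtcm = (cfg.root_mtcm + slope * (tmin - cfg.root_tmin)
            + np.sqrt(s2_e) * noise_dev)

    # warm side: correlated near-equal-rate pair
    tmax, mtwm = simulate_bivariate_traits(
        tree, cfg.s2_tmax, cfg.s2_mtwm, cfg.rho_warm,
        cfg.root_tmax, cfg.root_mtwm, rng)

    # climate grids: bio6 ramps north-south, bio5 west-east
    nrows, ncols = cfg.grid_shape
    cell = cfg.grid_cellsize
    xll, yll = 0.0, 0.0
    lat_c = yll + (np.arange(nrows)[::-1] + 0.5) * cell   # row 0 = north
    lon_c = xll + (np.arange(ncols) + 0.5) * cell
    bio6_vals = np.repeat(
        (cfg.bio6_at_equator + cfg.bio6_per_deg_lat * lat_c)[:, None],
        ncols, axis=1)
    bio5_vals = np.repeat(
        (cfg.bio5_west + cfg.bio5_per_deg_lon * (lon_c - xll))[None, :],
        nrows, axis=0)
    bio6_grid = ClimateGrid(bio6_vals, xll, yll, cell)
    bio5_grid = ClimateGrid(bio5_vals, xll, yll, cell)

    # species range centers chosen so grid extraction recovers the niche
    lat_span = nrows * cell
    lon_span = ncols * cell
    center_lat = (mtcm - cfg.bio6_at_equator) / cfg.bio6_per_deg_lat
    center_lon = (mtwm - cfg.bio5_west) / cfg.bio5_per_deg_lon + xll
    margin = 4 * cfg.occurrence_sd_deg
    center_lat = np.clip(center_lat, yll + margin, yll + lat_span - margin)
    center_lon = np.clip(center_lon, xll + margin, xll + lon_span - margin)

    occ_rows = []
    for i, sp in enumerate(species):
        k = cfg.n_occurrences
        lons = center_lon[i] + rng.normal(0, cfg.occurrence_sd_deg, k)
        lats = center_lat[i] + rng.normal(0, cfg.occurrence_sd_deg, k)
        lons = np.clip(lons, xll, xll + lon_span - 1e-9)
        lats = np.clip(lats, yll, yll + lat_span - 1e-9)
        b5 = bio5_grid.extract(lons, lats)
        b6 = bio6_grid.extract(lons, lats)
        occ_rows.append(pd.DataFrame({
            "species": sp, "longitude": lons, "latitude": lats,
            "bio5": b5, "bio6": b6}))
    occurrences = pd.concat(occ_rows, ignore_index=True)

    sites = pd.DataFrame({"species": species,
                          "longitude": center_lon, "latitude": center_lat})

    # raw measurement rows with repeats
    rows = []
    for i, sp in enumerate(species):
        for trait, val in (("T_min", tmin[i]), ("T_max", tmax[i])):
            k = int(rng.integers(1, cfg.n_measurements_max + 1))
            for v in val + rng.normal(0, cfg.measurement_sd, k):
                rows.append({"species": sp, "trait": trait, "value": v,
                             "hardening": strata[i], "group": groups[i]})
    trait_rows = pd.DataFrame(rows)

    truth = {
        "species": species,
        "T_min": dict(zip(species, tmin.tolist())),
        "T_max": dict(zip(species, tmax.tolist())),
        "MTCM": dict(zip(species, mtcm.tolist())),
        "MTWM": dict(zip(species, mtwm.tolist())),
        "hardening": dict(zip(species, strata.tolist())),
        "config": asdict(cfg),
    }
    return ScenarioBundle(tree=tree, trait_rows=trait_rows,
                          occurrences=occurrences, bio5_grid=bio5_grid,
                          bio6_grid=bio6_grid, sites=sites, truth=truth)


def write_scenario(bundle: ScenarioBundle, outdir) -> dict[str, str]:
    """Write the bundle in the pipeline's input formats.  Returns the file
    map (name -> path)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": out / "tree.nwk",
        "traits": out / "traits_raw.csv",
        "occurrences": out / "occurrences.csv",
        "sites": out / "sites.csv",
        "bio5": out / "bio5.asc",
        "bio6": out / "bio6.asc",
        "manifest": out / "manifest.json",
    }
    paths["tree"].write_text(write_newick(bundle.tree) + "\n")
    bundle.trait_rows.to_csv(paths["traits"], index=False,
                             float_format="%.10g")
    bundle.occurrences.to_csv(paths["occurrences"], index=False,
                              float_format="%.10g")
    bundle.sites.to_csv(paths["sites"], index=False, float_format="%.10g")
    bundle.bio5_grid.to_ascii(paths["bio5"])
    bundle.bio6_grid.to_ascii(paths["bio6"])
    manifest = {"config": bundle.truth.get("config", {}),
                "n_species": len(bundle.truth.get("species", []))}
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}
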