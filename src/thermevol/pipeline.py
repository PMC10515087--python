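"""Orchestration of the full analysis: the four rate comparisons across
taxonomic groups and hardening strata, absolute-rate reconstruction, and
the PGLS panels — from file inputs to delimited output tables.

Output tables are written twice: rounded to 2 decimals (mirroring the
published table layout) and at full precision.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ancrates import paired_rate_test, reconstruct_ancestors, tip_absolute_rates
from .errors import DataError, DegenerateTraitError, ParameterError, ThermevolError
from .models import fit_all_models, select_model
from .niche import (ClimateGrid, add_local_niche, assemble_analysis_table,
                    average_repeated_measurements, read_occurrences,
                    read_trait_rows, summarize_niche)
from .pgls import figure4_panels
from .phylo import Phylogeny, parse_newick, prune_to_taxa
from .ratecomp import compare_rates

__all__ = ["AnalysisConfig", "load_config", "build_inputs",
           "run_overall_rates", "run_absolute_rates", "run_pgls", "run_all"]

COMPARISONS = {
    "i": ("T_min", "MTCM"),
    "ii": ("T_max", "MTWM"),
    "iii": ("T_min", "T_max"),
    "iv": ("MTCM", "MTWM"),
}
GROUP_LEVELS = ("all", "angiosperm", "gymnosperm", "fern")
TYPE_LEVELS = {"all": None, "hardening": "hardened",
               "no_hardening": "non_hardened", "no_info": "unknown"}
MIN_STRATUM = 3


@dataclass
class AnalysisConfig:
    tree: str = ""
    traits: str = ""                 # raw measurement rows
    occurrences: str = ""            # either this ...
    niche_table: str = ""            # ... or a pre-summarized niche table
    sites: str = ""
    bio5_grid: str = ""
    bio6_grid: str = ""
    niche_variant: str = "mean"
    comparisons: tuple = ("i", "ii", "iii", "iv")
    groups: tuple = GROUP_LEVELS
    types: tuple = tuple(TYPE_LEVELS)
    lambda_mode: str = "fixed"
    pgls_lambda: float = 1.0
    time_mode: str = "terminal"
    out_dir: str = "thermevol_out"
    seed: int = 0

    def validate(self) -> None:
        for p in (self.tree, self.traits):
            if p and not Path(p).exists():
                raise DataError(f"input path does not exist: {p}")
        if not self.comparisons:
            raise DataError("at least one comparison must be requested")
        unknown = set(self.comparisons) - set(COMPARISONS)
        if unknown:
            raise DataError(f"unknown comparisons {sorted(unknown)}")


def load_config(path) -> AnalysisConfig:
    """Flat ``key = value`` text config; lists are comma-separated."""
    cfg = AnalysisConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise DataError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if not hasattr(cfg, key):
            raise DataError(f"{path}:{lineno}: unknown config key {key!r}")
        cur = getattr(cfg, key)
        if isinstance(cur, tuple):
            setattr(cfg, key, tuple(v.strip() for v in val.split(",")))
        elif isinstance(cur, int) and not isinstance(cur, bool):
            setattr(cfg, key, int(val))
        elif isinstance(cur, float):
            setattr(cfg, key, float(val))
        else:
            setattr(cfg, key, val)
    cfg.validate()
    return cfg


def _log(msg: str) -> None:
    print(f"[thermevol] {msg}", file=sys.stderr)


def _sha(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def build_inputs(cfg: AnalysisConfig) -> tuple[Phylogeny, pd.DataFrame]:
    """Load the tree and assemble the species-level analysis table."""
    tree = parse_newick(Path(cfg.tree).read_text())
    traits = average_repeated_measurements(read_trait_rows(cfg.traits))
    if cfg.niche_table:
        niche = pd.read_csv(cfg.niche_table, float_precision="round_trip")
    elif cfg.occurrences:
        niche = summarize_niche(read_occurrences(cfg.occurrences))
        if cfg.sites and cfg.bio5_grid and cfg.bio6_grid:
            niche = add_local_niche(
                niche, pd.read_csv(cfg.sites),
                ClimateGrid.from_ascii(cfg.bio5_grid),
                ClimateGrid.from_ascii(cfg.bio6_grid))
    else:
        raise DataError("config needs either 'occurrences' or 'niche_table'")
    table = assemble_analysis_table(traits, niche, cfg.niche_variant)
    _log(f"analysis table: {len(table)} species "
         f"({table.attrs.get('n_traits_unmatched', 0)} trait-only, "
         f"{table.attrs.get('n_niche_unmatched', 0)} niche-only dropped)")
    return tree, table


def _strata(table: pd.DataFrame, cfg: AnalysisConfig):
    for group in cfg.groups:
        gmask = (np.ones(len(table), dtype=bool) if group == "all"
                 else (table["group"] == group).to_numpy())
        for typ in cfg.types:
            level = TYPE_LEVELS.get(typ, typ)
            tmask = (np.ones(len(table), dtype=bool) if level is None
                     else (table["hardening"] == level).to_numpy())
            yield group, typ, table[gmask & tmask]


def run_overall_rates(cfg: AnalysisConfig, tree: Phylogeny | None = None,
                      table: pd.DataFrame | None = None) -> pd.DataFrame:
    """The published-table analysis: per (group x hardening type x
    comparison), prune to shared species and run the common- vs
    separate-rates LRT.  Strata below the minimum N become '-' rows."""
    if tree is None or table is None:
        tree, table = build_inputs(cfg)
    rows = []
    for comp in cfg.comparisons:
        ta_name, tb_name = COMPARISONS[comp]
        for group, typ, sub in _strata(table, cfg):
            base = {"comparison": comp, "trait_A": ta_name,
                    "trait_B": tb_name, "group": group, "type": typ}
            try:
                res = compare_rates(
                    tree, dict(zip(sub["species"], sub[ta_name])),
                    dict(zip(sub["species"], sub[tb_name])),
                    name_a=ta_name, name_b=tb_name)
                rows.append({**base, "n": res.n_species,
                             "sigma2_A": res.sigma2_A,
                             "sigma2_B": res.sigma2_B,
                             "lrt": res.lrt, "p": res.p_value,
                             "faster": res.faster_trait,
                             "tree_height": res.tree_height})
            except (ParameterError, DegenerateTraitError) as exc:
                _log(f"stratum {comp}/{group}/{typ}: {exc}")
                rows.append({**base, "n": np.nan, "sigma2_A": np.nan,
                             "sigma2_B": np.nan, "lrt": np.nan,
                             "p": np.nan, "faster": "-",
                             "tree_height": np.nan})
    return pd.DataFrame(rows)


def run_absolute_rates(cfg: AnalysisConfig, tree: Phylogeny | None = None,
                       table: pd.DataFrame | None = None):
    """Per trait: four-model fit, AIC selection, ancestral reconstruction
    on the transformed structure, tip absolute rates; per comparison: a
    paired t-test on ln rates over the shared species.

    Runs on the group='all', type='all' stratum of each comparison (the
    species-level analysis); returns (tiprate table, paired-test table,
    model-selection table)."""
    if tree is None or table is None:
        tree, table = build_inputs(cfg)
    tip_rows, test_rows, model_rows = [], [], []
    for comp in cfg.comparisons:
        ta, tb = COMPARISONS[comp]
        sub = table.dropna(subset=[ta, tb])
        sub = sub[sub["species"].isin(set(tree.tip_labels))]
        if len(sub) < MIN_STRATUM:
            _log(f"comparison {comp}: only {len(sub)} species, skipped")
            continue
        ptree = prune_to_taxa(tree, sub["species"])
        rates = {}
        for trait in (ta, tb):
            x = dict(zip(sub["species"], sub[trait]))
            fits = fit_all_models(ptree, x)
            best = select_model(fits)
            for f in fits:
                model_rows.append({
                    "comparison": comp, "trait": trait, "model": f.model,
                    "sigma2": f.sigma2, "lnL": f.lnL, "aic": f.aic,
                    "alpha": f.alpha, "lambda": f.lam,
                    "selected": f is best, "valid": f.valid})
            if not best.valid:
                _log(f"comparison {comp}, trait {trait}: degenerate fit, "
                     f"skipped")
                rates[trait] = None
                continue
            anc = reconstruct_ancestors(ptree, x, best)
            tr = tip_absolute_rates(ptree, x, anc, trait=trait,
                                    model_used=best.model,
                                    time_mode=cfg.time_mode)
            rates[trait] = tr
            tip_rows.extend({
                "comparison": comp, "species": r.species, "trait": r.trait,
                "tip_value": r.tip_value,
                "ancestor_estimate": r.ancestor_estimate,
                "branch_time": r.branch_time, "abs_rate": r.abs_rate,
                "model_used": r.model_used} for r in tr)
        if rates.get(ta) is not None and rates.get(tb) is not None:
            try:
                t = paired_rate_test(rates[ta], rates[tb],
                                     name_a=ta, name_b=tb)
                test_rows.append({
                    "comparison": comp, "trait_A": ta, "trait_B": tb,
                    "m": t.m, "mean_ln_rate_A": t.mean_ln_rate_A,
                    "mean_ln_rate_B": t.mean_ln_rate_B,
                    "t": t.t_statistic, "df": t.df, "p": t.p_value,
                    "n_excluded_zero": t.n_excluded_zero})
            except ParameterError as exc:
                _log(f"comparison {comp}: paired test skipped: {exc}")
    return (pd.DataFrame(tip_rows), pd.DataFrame(test_rows),
            pd.DataFrame(model_rows))


def run_pgls(cfg: AnalysisConfig, tree: Phylogeny | None = None,
             table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Six-panel PGLS: {T_min~MTCM, T_max~MTWM} x {all, hardened,
    non_hardened}."""
    if tree is None or table is None:
        tree, table = build_inputs(cfg)
    fits = figure4_panels(table, tree, lambda_mode=cfg.lambda_mode,
                          lam=cfg.pgls_lambda, log=_log)
    return pd.DataFrame([{
        "panel": f"{f.response}~{f.predictor}", "stratum": f.stratum,
        "n": f.n, "slope": f.slope, "intercept": f.intercept,
        "r2": f.r2, "p": f.p_value, "lambda": f.lambda_used} for f in fits])


def _write(df: pd.DataFrame, outdir: Path, name: str) -> None:
    df.to_csv(outdir / f"{name}_full.csv", index=False, float_format="%.12g")
    rounded = df.copy()
    for c in rounded.columns:
        if pd.api.types.is_float_dtype(rounded[c]):
            rounded[c] = rounded[c].round(2)
    rounded.to_csv(outdir / f"{name}.csv", index=False, na_rep="-")


def run_all(cfg: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Full analysis with a run manifest; returns the result tables."""
    cfg.validate()
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, table = build_inputs(cfg)

    results = {"overall_rates": run_overall_rates(cfg, tree, table)}
    tips, tests, msel = run_absolute_rates(cfg, tree, table)
    results.update({"tip_rates": tips, "paired_tests": tests,
                    "model_selection": msel})
    results["pgls"] = run_pgls(cfg, tree, table)

    for name, df in results.items():
        _write(df, outdir, name)
    manifest = {
        "version": __version__, "seed": cfg.seed,
        "niche_variant": cfg.niche_variant,
        "lambda_mode": cfg.lambda_mode, "time_mode": cfg.time_mode,
        "inputs": {k: {"path": p, "sha256_16": _sha(p)}
                   for k, p in (("tree", cfg.tree), ("traits", cfg.traits),
                                ("occurrences", cfg.occurrences),
                                ("niche_table", cfg.niche_table))
                   if p},
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n")
    _log(f"wrote {len(results)} result tables to {outdir}")
    return results
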