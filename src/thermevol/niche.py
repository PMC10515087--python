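"""Species-level analysis-table assembly: climatic-niche summaries from
occurrence records, averaging of repeated physiological measurements,
hardening/group stratification, and a small ESRI-ASCII climate-grid
reader for synthetic surfaces.

Percentiles use linear interpolation between order statistics
(``numpy.percentile`` default) so summaries are reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "ClimateGrid", "validate_occurrences", "average_repeated_measurements",
    "summarize_niche", "extract_grid_values", "assemble_analysis_table",
    "read_trait_rows", "read_occurrences",
    "HARDENING_LEVELS", "GROUPS", "NICHE_VARIANTS",
]

HARDENING_LEVELS = ("hardened", "non_hardened", "unknown")
GROUPS = ("angiosperm", "gymnosperm", "fern", "bryophyte")
NICHE_VARIANTS = ("mean", "tail", "local")

_TRAIT_KINDS = ("T_min", "T_max")


# ---------------------------------------------------------------------------
# Gridded climate surfaces (ESRI ASCII)
# ---------------------------------------------------------------------------

@dataclass
class ClimateGrid:
    """Cell-registered raster; row 0 is the northernmost row.

    Lookup is nearest-cell: a point maps to the cell containing it, with
    boundary ties resolved toward the cell with the larger index along
    each axis (east/north).
    """

    values: np.ndarray      # (nrows, ncols)
    xll: float              # west edge of the grid
    yll: float              # south edge
    cellsize: float
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def extract(self, lons, lats) -> np.ndarray:
        """Cell values at the given coordinates; NaN for out-of-extent
        points or nodata cells."""
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        col = np.floor((lons - self.xll) / self.cellsize).astype(int)
        row_s = np.floor((lats - self.yll) / self.cellsize).astype(int)
        # points exactly on the top/right outer edge belong to the last cell
        col = np.where((lons == self.xll + self.ncols * self.cellsize),
                       self.ncols - 1, col)
        row_s = np.where((lats == self.yll + self.nrows * self.cellsize),
                         self.nrows - 1, row_s)
        ok = (col >= 0) & (col < self.ncols) & (row_s >= 0) & (row_s < self.nrows)
        out = np.full(lons.shape, np.nan)
        r = self.nrows - 1 - row_s[ok]
        vals = self.values[r, col[ok]]
        vals = np.where(vals == self.nodata, np.nan, vals)
        out[ok] = vals
        return out

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - 1 - row + 0.5) * self.cellsize
        return lon, lat

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_ascii(cls, path) -> "ClimateGrid":
        lines = Path(path).read_text().splitlines()
        hdr: dict[str, float] = {}
        i = 0
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value"):
                hdr[parts[0].lower()] = float(parts[1])
                i += 1
            else:
                break
        for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if req not in hdr:
                raise DataError(f"ESRI ASCII grid missing header field {req!r}")
        vals = np.loadtxt(lines[i:], dtype=float)
        vals = vals.reshape(int(hdr["nrows"]), int(hdr["ncols"]))
        return cls(values=vals, xll=hdr["xllcorner"], yll=hdr["yllcorner"],
                   cellsize=hdr["cellsize"],
                   nodata=hdr.get("nodata_value", -9999.0))

    def to_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xll:.10g}\n")
            fh.write(f"yllcorner {self.yll:.10g}\n")
            fh.write(f"cellsize {self.cellsize:.10g}\n")
            fh.write(f"NODATA_value {self.nodata:.10g}\n")
            np.savetxt(fh, self.values, fmt="%.10g")


def extract_grid_values(grid: ClimateGrid, lons, lats) -> np.ndarray:
    """Functional alias for :meth:`ClimateGrid.extract`."""
    return grid.extract(lons, lats)


# ---------------------------------------------------------------------------
# Occurrence records and niche summaries
# ---------------------------------------------------------------------------

def validate_occurrences(occ: pd.DataFrame) -> pd.DataFrame:
    """Check coordinate ranges and bio5 >= bio6 per record; raises DataError
    with offending row indices."""
    req = {"species", "longitude", "latitude", "bio5", "bio6"}
    missing = req - set(occ.columns)
    if missing:
        raise DataError(f"occurrence table missing columns {sorted(missing)}")
    bad_lon = ~occ["longitude"].between(-180, 180)
    bad_lat = ~occ["latitude"].between(-90, 90)
    bad_tmp = occ["bio5"] < occ["bio6"]
    for name, mask in (("longitude", bad_lon), ("latitude", bad_lat),
                       ("bio5 < bio6", bad_tmp)):
        if mask.any():
            raise DataError(
                f"invalid {name} in occurrence rows {list(occ.index[mask][:10])}")
    return occ


def summarize_niche(occ: pd.DataFrame, *, upper_mode: str = "percentile"
                    ) -> pd.DataFrame:
    """Per-species climatic-niche summaries.

    Columns of the result: species, n_occurrences, mean_MTWM, mean_MTCM,
    upper_MTWM (90th percentile of bio5), lower_MTCM (10th percentile of
    bio6).  ``upper_mode='tail_mean'`` instead averages the values at or
    beyond the respective percentile (the literal "top 90%" reading).
    """
    if len(occ) == 0:
        raise DataError("empty occurrence set")
    validate_occurrences(occ)
    if upper_mode not in ("percentile", "tail_mean"):
        raise DataError(f"unknown upper_mode {upper_mode!r}")

    def _summ(g: pd.DataFrame) -> pd.Series:
        b5 = g["bio5"].to_numpy(float)
        b6 = g["bio6"].to_numpy(float)
        q5 = float(np.percentile(b5, 90))
        q6 = float(np.percentile(b6, 10))
        if upper_mode == "tail_mean":
            upper = float(b5[b5 >= q5].mean())
            lower = float(b6[b6 <= q6].mean())
        else:
            upper, lower = q5, q6
        return pd.Series({
            "n_occurrences": len(g),
            "mean_MTWM": float(b5.mean()),
            "mean_MTCM": float(b6.mean()),
            "upper_MTWM": upper,
            "lower_MTCM": lower,
        })

    out = (occ.groupby("species", sort=True)
              .apply(_summ, include_groups=False)
              .reset_index())
    out["n_occurrences"] = out["n_occurrences"].astype(int)
    return out


def add_local_niche(niche: pd.DataFrame, sites: pd.DataFrame,
                    bio5_grid: ClimateGrid, bio6_grid: ClimateGrid
                    ) -> pd.DataFrame:
    """Attach local_MTWM/local_MTCM from experimental-site coordinates
    (columns species, longitude, latitude) looked up on the grids."""
    s = sites.drop_duplicates("species")
    loc5 = bio5_grid.extract(s["longitude"].to_numpy(), s["latitude"].to_numpy())
    loc6 = bio6_grid.extract(s["longitude"].to_numpy(), s["latitude"].to_numpy())
    local = pd.DataFrame({"species": s["species"].to_numpy(),
                          "local_MTWM": loc5, "local_MTCM": loc6})
    return niche.merge(local, on="species", how="left")


# ---------------------------------------------------------------------------
# Trait table
# ---------------------------------------------------------------------------

def average_repeated_measurements(rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw measurement rows (species, trait, value[, hardening,
    group]) to one row per species with T_min/T_max columns.

    Repeated measurements are averaged arithmetically.  Conflicting
    hardening labels within a species resolve to 'unknown' with a warning;
    conflicting group labels keep the most frequent.
    """
    req = {"species", "trait", "value"}
    missing = req - set(rows.columns)
    if missing:
        raise DataError(f"trait rows missing columns {sorted(missing)}")
    bad_trait = ~rows["trait"].isin(_TRAIT_KINDS)
    if bad_trait.any():
        raise DataError(f"unknown trait kinds in rows "
                        f"{list(rows.index[bad_trait][:10])}")
    vals = pd.to_numeric(rows["value"], errors="coerce")
    if vals.isna().any():
        raise DataError(f"non-numeric trait values in rows "
                        f"{list(rows.index[vals.isna()][:10])}")
    rows = rows.assign(value=vals)

    wide = (rows.groupby(["species", "trait"])["value"].mean()
                .unstack("trait"))
    for t in _TRAIT_KINDS:
        if t not in wide.columns:
            wide[t] = np.nan
    out = wide[list(_TRAIT_KINDS)].reset_index()

    if "hardening" in rows.columns:
        def _hard(g):
            labs = set(g.dropna().astype(str))
            labs.discard("unknown")
            if len(labs) == 1:
                return labs.pop()
            if len(labs) > 1:
                return "conflict"
            return "unknown"
        h = rows.groupby("species")["hardening"].apply(_hard)
        n_conf = int((h == "conflict").sum())
        if n_conf:
            warnings.warn(f"{n_conf} species with conflicting hardening "
                          f"labels set to 'unknown'", stacklevel=2)
        out["hardening"] = h.replace("conflict", "unknown").reindex(
            out["species"]).to_numpy()
    else:
        out["hardening"] = "unknown"

    if "group" in rows.columns:
        g = rows.groupby("species")["group"].agg(
            lambda s: s.mode().iloc[0] if s.notna().any() else "angiosperm")
        out["group"] = g.reindex(out["species"]).to_numpy()
    else:
        out["group"] = "angiosperm"

    both = out["T_min"].notna() & out["T_max"].notna()
    bad = both & (out["T_min"] >= out["T_max"])
    if bad.any():
        warnings.warn(f"{int(bad.sum())} species with T_min >= T_max",
                      stacklevel=2)
    return out


def assemble_analysis_table(traits: pd.DataFrame, niche: pd.DataFrame,
                            niche_variant: str = "mean") -> pd.DataFrame:
    """Inner-join traits with niche summaries and select one niche variant.

    Result columns: species, T_min, T_max, MTCM, MTWM, hardening, group.
    Join losses on either side are reported in the frame's ``attrs``.
    """
    if niche_variant not in NICHE_VARIANTS:
        raise DataError(f"unknown niche variant {niche_variant!r}")
    colmap = {
        "mean": ("mean_MTCM", "mean_MTWM"),
        "tail": ("lower_MTCM", "upper_MTWM"),
        "local": ("local_MTCM", "local_MTWM"),
    }
    ccol, wcol = colmap[niche_variant]
    for c in (ccol, wcol):
        if c not in niche.columns:
            raise DataError(f"niche table lacks column {c!r} "
                            f"needed for variant {niche_variant!r}")
    merged = traits.merge(niche[["species", ccol, wcol]], on="species",
                          how="inner")
    merged = merged.rename(columns={ccol: "MTCM", wcol: "MTWM"})
    cols = ["species", "T_min", "T_max", "MTCM", "MTWM", "hardening", "group"]
    merged = merged[[c for c in cols if c in merged.columns]]
    merged.attrs["n_traits_unmatched"] = int(
        (~traits["species"].isin(niche["species"])).sum())
    merged.attrs["n_niche_unmatched"] = int(
        (~niche["species"].isin(traits["species"])).sum())
    return merged.sort_values("species", ignore_index=True)


# ---------------------------------------------------------------------------
# Delimited-text readers
# ---------------------------------------------------------------------------

def read_trait_rows(path) -> pd.DataFrame:
    """Raw measurement rows: species, trait (T_min|T_max), value
    [, hardening, group].  CSV or TSV by extension."""
    df = _read_delim(path)
    return df


def read_occurrences(path) -> pd.DataFrame:
    """Occurrence-climate records: species, longitude, latitude, bio5, bio6."""
    return validate_occurrences(_read_delim(path))


def _read_delim(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        # round_trip parsing keeps write->read cycles bitwise exact
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:
        raise DataError(f"failed to read {path}: {exc}") from exc
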