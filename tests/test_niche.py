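import numpy as np
import pandas as pd
import pytest

from thermevol.errors import DataError
from thermevol.niche import (ClimateGrid, assemble_analysis_table,
                             average_repeated_measurements,
                             extract_grid_values, summarize_niche,
                             validate_occurrences)


def occ_frame(species, bio5, bio6, lon=0.0, lat=0.0):
    k = len(bio5)
    return pd.DataFrame({
        "species": [species] * k,
        "longitude": np.full(k, lon), "latitude": np.full(k, lat),
        "bio5": bio5, "bio6": bio6})


class TestAveraging:
    def test_mean_of_repeats(self):
        rows = pd.DataFrame({
            "species": ["X", "X"], "trait": ["T_min", "T_min"],
            "value": [-8.0, -10.0]})
        out = average_repeated_measurements(rows)
        assert out.loc[out.species == "X", "T_min"].iloc[0] == pytest.approx(-9.0)

    def test_single_passthrough(self):
        rows = pd.DataFrame({"species": ["Y"], "trait": ["T_max"],
                             "value": [42.0]})
        out = average_repeated_measurements(rows)
        assert out["T_max"].iloc[0] == 42.0
        assert np.isnan(out["T_min"].iloc[0])

    def test_grouping_oracle(self):
        rng = np.random.default_rng(0)
        n_rows = 1000
        species = rng.choice([f"sp{i}" for i in range(300)], n_rows)
        trait = rng.choice(["T_min", "T_max"], n_rows)
        rows = pd.DataFrame({"species": species, "trait": trait,
                             "value": rng.standard_normal(n_rows)})
        out = average_repeated_measurements(rows)
        distinct_pairs = len(set(zip(species, trait)))
        n_values = out[["T_min", "T_max"]].notna().sum().sum()
        assert n_values == distinct_pairs
        assert len(out) == len(set(species))

    def test_non_numeric_value_errors(self):
        rows = pd.DataFrame({"species": ["X"], "trait": ["T_min"],
                             "value": ["cold"]})
        with pytest.raises(DataError, match="non-numeric"):
            average_repeated_measurements(rows)

    def test_conflicting_hardening_becomes_unknown(self):
        rows = pd.DataFrame({
            "species": ["X", "X"], "trait": ["T_min", "T_min"],
            "value": [1.0, 2.0], "hardening": ["hardened", "non_hardened"]})
        with pytest.warns(UserWarning, match="conflicting hardening"):
            out = average_repeated_measurements(rows)
        assert out["hardening"].iloc[0] == "unknown"

    def test_tmin_above_tmax_warns(self):
        rows = pd.DataFrame({
            "species": ["X", "X"], "trait": ["T_min", "T_max"],
            "value": [50.0, 10.0]})
        with pytest.warns(UserWarning, match="T_min >= T_max"):
            average_repeated_measurements(rows)


class TestSummarizeNiche:
    def test_single_occurrence(self):
        out = summarize_niche(occ_frame("X", [30.0], [2.0]))
        row = out.iloc[0]
        for col in ("mean_MTWM", "upper_MTWM"):
            assert row[col] == 30.0
        for col in ("mean_MTCM", "lower_MTCM"):
            assert row[col] == 2.0
        assert row["n_occurrences"] == 1

    def test_linear_interpolation_percentile(self):
        bio6 = np.arange(11.0)          # 0..10
        out = summarize_niche(occ_frame("X", bio6 + 30.0, bio6))
        assert out["lower_MTCM"].iloc[0] == pytest.approx(1.0)
        assert out["upper_MTWM"].iloc[0] == pytest.approx(39.0)

    def test_mean_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        bio6 = rng.normal(0, 5, 500)
        bio5 = bio6 + 25.0
        out = summarize_niche(occ_frame("X", bio5, bio6))
        assert out["mean_MTCM"].iloc[0] == pytest.approx(bio6.mean(), abs=1e-9)

    def test_tail_widens_niche(self):
        rng = np.random.default_rng(4)
        frames = [occ_frame(f"sp{i}", rng.normal(30, 3, 40),
                            rng.normal(0, 3, 40)) for i in range(20)]
        out = summarize_niche(pd.concat(frames, ignore_index=True))
        assert (out["lower_MTCM"] <= out["mean_MTCM"] + 1e-12).all()
        assert (out["upper_MTWM"] >= out["mean_MTWM"] - 1e-12).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        occ = occ_frame("X", rng.normal(30, 2, 50), rng.normal(0, 2, 50))
        a = summarize_niche(occ)
        b = summarize_niche(occ.sample(frac=1.0, random_state=9)
                            .reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)

    def test_tail_mean_mode(self):
        bio6 = np.arange(10.0)
        out = summarize_niche(occ_frame("X", bio6 + 30.0, bio6),
                              upper_mode="tail_mean")
        q10 = np.percentile(bio6, 10)
        assert out["lower_MTCM"].iloc[0] == pytest.approx(
            bio6[bio6 <= q10].mean())

    def test_empty_errors(self):
        with pytest.raises(DataError):
            summarize_niche(occ_frame("X", [], []))

    def test_invalid_coordinates_error(self):
        occ = occ_frame("X", [30.0], [2.0], lon=500.0)
        with pytest.raises(DataError, match="longitude"):
            validate_occurrences(occ)

    def test_bio5_below_bio6_error(self):
        occ = occ_frame("X", [1.0], [10.0])
        with pytest.raises(DataError, match="bio5 < bio6"):
            validate_occurrences(occ)


class TestGrid:
    def _gradient_grid(self):
        # value = 2 * lat at cell centers, 10x10, 1-degree cells at origin
        vals = np.repeat((2.0 * (np.arange(10)[::-1] + 0.5))[:, None], 10, 1)
        return ClimateGrid(vals, xll=0.0, yll=0.0, cellsize=1.0)

    def test_cell_center_lookup(self):
        g = self._gradient_grid()
        lon, lat = g.cell_center(3, 4)
        assert extract_grid_values(g, [lon], [lat])[0] == pytest.approx(2 * lat)

    def test_out_of_extent_missing(self):
        g = self._gradient_grid()
        v = extract_grid_values(g, [-5.0, 2.0], [2.0, -3.0])
        assert np.isnan(v).all()

    def test_analytic_gradient(self):
        g = self._gradient_grid()
        rng = np.random.default_rng(6)
        lons = rng.uniform(0, 10, 100)
        lats = rng.uniform(0, 10, 100)
        got = extract_grid_values(g, lons, lats)
        centers = np.floor(lats) + 0.5
        assert np.allclose(got, 2.0 * centers)

    def test_edge_tie_goes_to_larger_index(self):
        g = self._gradient_grid()
        # lat exactly on the boundary between cells [2.5] and [3.5]
        v = extract_grid_values(g, [0.5], [3.0])[0]
        assert v == pytest.approx(2 * 3.5)

    def test_ascii_roundtrip(self, tmp_path):
        g = self._gradient_grid()
        p = tmp_path / "g.asc"
        g.to_ascii(p)
        g2 = ClimateGrid.from_ascii(p)
        assert np.allclose(g.values, g2.values)
        assert g2.cellsize == g.cellsize
        assert g2.xll == g.xll


class TestAssemble:
    def _traits(self, species):
        return pd.DataFrame({
            "species": species,
            "T_min": -5.0, "T_max": 40.0,
            "hardening": "hardened", "group": "angiosperm"})

    def _niche(self, species):
        return pd.DataFrame({
            "species": species, "n_occurrences": 3,
            "mean_MTWM": 30.0, "mean_MTCM": 1.0,
            "upper_MTWM": 33.0, "lower_MTCM": -2.0})

    def test_inner_join(self):
        out = assemble_analysis_table(self._traits(["A", "B"]),
                                      self._niche(["B", "C"]))
        assert list(out["species"]) == ["B"]
        assert out.attrs["n_traits_unmatched"] == 1
        assert out.attrs["n_niche_unmatched"] == 1

    def test_tail_variant_selects_tail_columns(self):
        out = assemble_analysis_table(self._traits(["A"]), self._niche(["A"]),
                                      niche_variant="tail")
        assert out["MTCM"].iloc[0] == -2.0
        assert out["MTWM"].iloc[0] == 33.0

    def test_join_oracle(self):
        rng = np.random.default_rng(7)
        all_sp = [f"sp{i}" for i in range(300)]
        t_sp = [s for s in all_sp if rng.random() > 0.1]
        n_sp = [s for s in all_sp if rng.random() > 0.1]
        out = assemble_analysis_table(self._traits(t_sp), self._niche(n_sp))
        assert len(out) == len(set(t_sp) & set(n_sp))

    def test_local_variant_requires_columns(self):
        with pytest.raises(DataError, match="local_MTCM"):
            assemble_analysis_table(self._traits(["A"]), self._niche(["A"]),
                                    niche_variant="local")

    def test_stratum_counts_sum(self):
        rng = np.random.default_rng(8)
        species = [f"sp{i}" for i in range(120)]
        traits = self._traits(species).assign(
            hardening=rng.choice(["hardened", "non_hardened", "unknown"], 120))
        out = assemble_analysis_table(traits, self._niche(species))
        counts = out["hardening"].value_counts()
        assert counts.sum() == len(out)
        assert set(counts.index) <= {"hardened", "non_hardened", "unknown"}
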