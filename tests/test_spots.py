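"""Counting rules, nascent classification and transcription-site filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subpoisson.spots import (
    CountingConfig,
    build_count_table,
    classify_nascent,
    count_cell,
    count_spots,
    filter_ts_cells,
    normalize_intensities,
    resolve_ts_compartment,
    single_molecule_threshold,
)


def _spot_row(cid, channel, compartment, intensity=1.0, x=0.0, y=0.0, z=0.0, rep="r1"):
    return {
        "cell_id": cid,
        "replicate_id": rep,
        "channel": channel,
        "x": x,
        "y": y,
        "z": z,
        "intensity": intensity,
        "compartment": compartment,
    }


class TestNormalization:
    def test_median_normalization(self, toy_spots):
        out = normalize_intensities(toy_spots)
        assert list(out["intensity"]) == [0.5, 1.0, 1.5, 1.0, 1.0]

    def test_equal_intensities_normalize_to_one(self, toy_spots):
        toy_spots["intensity"] = 3.0
        assert (normalize_intensities(toy_spots)["intensity"] == 1.0).all()

    def test_missing_cytoplasmic_reference_names_replicate(self, toy_spots):
        toy_spots["compartment"] = "nuclear"
        with pytest.raises(ValueError, match="r1"):
            normalize_intensities(toy_spots)

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(0.01, 100),
        intensities=st.lists(st.floats(0.1, 50), min_size=3, max_size=30),
    )
    def test_scale_invariance(self, scale, intensities):
        df = pd.DataFrame(
            [_spot_row("c", "mRNA", "cytoplasmic", i) for i in intensities]
        )
        a = normalize_intensities(df)["intensity"].to_numpy()
        df2 = df.copy()
        df2["intensity"] *= scale
        b = normalize_intensities(df2)["intensity"].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_ts_channel_untouched(self, toy_spots):
        toy_spots.loc[0, "channel"] = "TS"
        toy_spots.loc[0, "intensity"] = 7.0
        out = normalize_intensities(toy_spots)
        assert out.loc[0, "intensity"] == 7.0


class TestCountingRules:
    def test_three_methods_on_reference_example(self):
        """Threshold 1.4: {0.9, 1.2, 3.0} -> spot 3, intensity 5.1, hybrid 5.0."""
        ints = np.array([0.9, 1.2, 3.0])
        assert count_spots(ints, 1.4, "spot") == 3
        assert count_spots(ints, 1.4, "intensity") == pytest.approx(5.1)
        assert count_spots(ints, 1.4, "hybrid") == pytest.approx(5.0)

    def test_empty_cell_counts_zero(self):
        for method in ("spot", "intensity", "hybrid"):
            assert count_spots(np.array([]), 1.4, method) == 0.0

    def test_count_cell_uses_reference_percentile(self):
        cell = pd.DataFrame(
            [_spot_row("c", "mRNA", "cytoplasmic", i) for i in (0.9, 1.2, 3.0)]
        )
        ref = np.linspace(0.6, 1.4, 101)  # 95th percentile = 1.36
        got = count_cell(cell, ref, CountingConfig("hybrid"))
        assert got == pytest.approx(1 + 1 + 3.0)

    def test_hybrid_equals_brute_force_rule(self):
        rng = np.random.default_rng(5)
        ints = rng.lognormal(0, 0.6, 200)
        thr = 1.5
        brute = sum(1.0 if i < thr else i for i in ints)
        assert count_spots(ints, thr, "hybrid") == pytest.approx(brute)

    def test_hybrid_equals_spot_count_when_all_dim(self):
        ints = np.full(17, 0.8)
        assert count_spots(ints, 1.0, "hybrid") == count_spots(ints, 1.0, "spot")

    @settings(max_examples=20, deadline=None)
    @given(st.permutations(list(range(8))))
    def test_permutation_invariance(self, order):
        ints = np.array([0.5, 0.9, 1.1, 1.3, 2.0, 3.5, 0.7, 1.0])
        for method in ("spot", "intensity", "hybrid"):
            assert count_spots(ints[order], 1.2, method) == pytest.approx(
                count_spots(ints, 1.2, method)
            )

    def test_counting_is_replicate_local(self, toy_spots):
        other = pd.DataFrame(
            [_spot_row("z1", "mRNA", "cytoplasmic", i, rep="r2") for i in (9.0, 11.0)]
        )
        both = pd.concat([toy_spots, other], ignore_index=True)
        thr_one = single_molecule_threshold(normalize_intensities(toy_spots))["r1"]
        thr_two = single_molecule_threshold(normalize_intensities(both))["r1"]
        assert thr_one == pytest.approx(thr_two)


class TestNascentClassification:
    def _table(self, distances, rep="r1"):
        rows = [_spot_row("c1", "TS", "nuclear", 5.0)]
        rows += [
            _spot_row("c1", "mRNA", "nuclear", 1.0, x=d, rep=rep) for d in distances
        ]
        return pd.DataFrame(rows)

    def test_well_separated_modes(self):
        df = self._table([0.10, 0.12, 0.15, 2.0, 2.2, 2.5])
        with pytest.warns(UserWarning):  # < 10 distances: fallback path
            labels, cutoffs = classify_nascent(df)
        cut = cutoffs["r1"]
        assert 0.15 < cut < 2.0
        assert (labels[df["channel"] == "mRNA"] == "nascent").sum() == 3

    def test_no_ts_anywhere_means_all_mature(self):
        df = self._table([0.1, 0.2, 1.5])
        df = df[df["channel"] == "mRNA"].reset_index(drop=True)
        labels, cutoffs = classify_nascent(df)
        assert (labels == "mature").all()
        assert cutoffs == {}

    def test_cell_without_ts_gets_mature_labels(self):
        df = self._table([0.1] * 8 + [2.0] * 8)
        lone = pd.DataFrame([_spot_row("c9", "mRNA", "nuclear", 1.0, x=0.05)])
        labels, _ = classify_nascent(pd.concat([df, lone], ignore_index=True))
        assert labels.iloc[-1] == "mature"

    def test_generator_ground_truth_recovery(self, small_population):
        """Default synthetic geometry: >= 99% of nascent/mature labels recovered."""
        _, _, _, spots = small_population
        labels, _ = classify_nascent(spots)
        nuc = spots["true_label"].isin(["nascent", "mature_nuclear"])
        truth = spots.loc[nuc, "true_label"].map(
            {"nascent": "nascent", "mature_nuclear": "mature"}
        )
        assert (labels[nuc] == truth).mean() >= 0.99


class TestTSFilters:
    def test_filter_rules(self, simple_cells):
        cells = simple_cells(["ok", "many", "cyto"])
        spots = pd.DataFrame(
            [
                _spot_row("ok", "TS", "nuclear"),
                _spot_row("many", "TS", "nuclear"),
                _spot_row("many", "TS", "nuclear", x=0.1),
                _spot_row("many", "TS", "nuclear", x=0.2),
                _spot_row("cyto", "TS", "cytoplasmic", x=4.0),
            ]
        )
        out = filter_ts_cells(cells, spots).set_index("cell_id")
        assert not out.loc["ok", "excluded"]
        assert out.loc["many", "exclusion_reason"] == "too many TS"
        assert out.loc["cyto", "exclusion_reason"] == "cytoplasmic TS"

    def test_binucleated_empty_nucleus_excluded(self, simple_cells):
        cells = simple_cells(["bi"], n_nuclei=2)
        spots = pd.DataFrame([_spot_row("bi", "TS", "nuclear", x=0.0)])
        out = filter_ts_cells(cells, spots)
        assert out.loc[0, "excluded"]
        assert out.loc[0, "exclusion_reason"] == "no TS"


class TestCompartmentResolution:
    def _cell_and_spots(self, simple_cells, ts_x):
        cells = simple_cells(["c"], radius=1.0)
        spots = pd.DataFrame(
            [
                _spot_row("c", "TS", "nuclear", x=ts_x),
                _spot_row("c", "mRNA", "cytoplasmic", x=1.1),
            ]
        )
        return cells, spots

    def test_expand_grows_radius_and_reassigns(self, simple_cells):
        cells, spots = self._cell_and_spots(simple_cells, ts_x=1.2)
        out_cells, out_spots = resolve_ts_compartment(cells, spots, "expand")
        assert out_cells.loc[0, "nuc1_r"] == pytest.approx(1.2)
        assert out_spots.loc[1, "compartment"] == "nuclear"

    def test_filter_mode_excludes(self, simple_cells):
        cells, spots = self._cell_and_spots(simple_cells, ts_x=1.2)
        out_cells, _ = resolve_ts_compartment(cells, spots, "filter")
        assert out_cells.loc[0, "excluded"]
        assert out_cells.loc[0, "exclusion_reason"] == "TS outside nucleus"

    def test_ts_inside_changes_nothing(self, simple_cells):
        cells, spots = self._cell_and_spots(simple_cells, ts_x=0.8)
        out_cells, out_spots = resolve_ts_compartment(cells, spots, "expand")
        assert out_cells.loc[0, "nuc1_r"] == pytest.approx(1.0)
        assert out_spots.loc[1, "compartment"] == "cytoplasmic"


class TestCountTable:
    def test_hand_built_table_exact_counts(self, simple_cells):
        cells = simple_cells(["a", "b", "c"])
        rows = []
        for cid in ("a", "b", "c"):
            rows.append(_spot_row(cid, "TS", "nuclear"))
        # a: 1 nascent + 1 mature nuclear + 2 cytoplasmic; b: 1 cyt; c: none
        rows += [
            _spot_row("a", "mRNA", "nuclear", 1.0, x=0.05),
            _spot_row("a", "mRNA", "nuclear", 1.0, x=0.9),
            _spot_row("a", "mRNA", "cytoplasmic", 1.0, x=3.0),
            _spot_row("a", "mRNA", "cytoplasmic", 1.0, x=-3.0),
            _spot_row("b", "mRNA", "cytoplasmic", 1.0, x=2.0),
        ]
        # pad the replicate's distance pool so the cutoff path is exercised
        for k in range(8):
            rows.append(_spot_row("b", "mRNA", "nuclear", 1.0, x=0.04 + 0.01 * k))
            rows.append(_spot_row("c", "mRNA", "nuclear", 1.0, x=0.85 + 0.01 * k))
        spots = pd.DataFrame(rows)
        table = build_count_table(
            cells, spots, CountingConfig("spot"), ts_mode="none"
        ).set_index("cell_id")
        assert table.loc["a", "nascent"] == 1
        assert table.loc["a", "mature_nuclear"] == 1
        assert table.loc["a", "cytoplasmic"] == 2
        assert table.loc["b", "nascent"] == 8
        assert table.loc["c", "mature_nuclear"] == 8
        assert (
            table["total"]
            == table["nascent"] + table["mature_nuclear"] + table["cytoplasmic"]
        ).all()

    def test_spot_method_totals_equal_raw_spot_numbers(self, small_population):
        _, cells, truth, spots = small_population
        table = build_count_table(
            cells, spots.drop(columns="true_label"), CountingConfig("spot"),
            ts_mode="none",
        )
        merged = table.merge(truth, on="cell_id")
        assert (merged["cytoplasmic_x"] == merged["cytoplasmic_y"]).all()
        assert (
            merged["nascent"] + merged["mature_nuclear"] == merged["nuclear"]
        ).all()

    def test_hybrid_close_to_truth_on_generator_output(self, small_population):
        _, cells, truth, spots = small_population
        table = build_count_table(
            cells, spots.drop(columns="true_label"), CountingConfig("hybrid"),
            ts_mode="none",
        )
        merged = table.merge(truth, on="cell_id")
        got = merged["cytoplasmic_x"].sum()
        want = merged["cytoplasmic_y"].sum()
        # intensity noise only enters through the few spots above the 95th
        # percentile, so totals agree to a few percent
        assert got == pytest.approx(want, rel=0.05)
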