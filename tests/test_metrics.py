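"""Occupancy, duration statistics, metrics table, and network aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liprot.contacts import ContactParams, compute_contact_series
from liprot.errors import ParameterError
from liprot.fixtures import make_scripted_contact_system
from liprot.metrics import (
    DEFAULT_RESIDUE_CLASSES,
    build_metrics_table,
    build_network,
    contact_durations,
    load_residue_classes,
    occupancy,
)


class TestOccupancy:
    def test_single_molecule_series(self):
        assert occupancy(np.array([1, 0, 1, 1], dtype=bool)) == 0.75

    def test_or_across_molecules(self):
        pres = np.array([[1, 0], [0, 0], [0, 0], [0, 1]], dtype=bool)
        assert occupancy(pres) == 0.5

    def test_all_zero(self):
        assert occupancy(np.zeros((4, 2), dtype=bool)) == 0.0

    def test_no_frames_rejected(self):
        with pytest.raises(ParameterError):
            occupancy(np.zeros((0, 2), dtype=bool))


def _rle_durations_oracle(series, dt_ps):
    """Plain-python run-length oracle."""
    runs, current = [], 0
    for v in series:
        if v:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return [r * dt_ps / 1000.0 for r in runs]


class TestContactDurations:
    def test_two_events(self):
        st_ = contact_durations([1, 1, 0, 1], dt_ps=1000)
        np.testing.assert_allclose(sorted(st_.events_ns), [1.0, 2.0])
        assert st_.longest_ns == 2.0
        assert st_.mean_ns == 1.5
        assert st_.n_events == 2

    def test_single_full_event(self):
        st_ = contact_durations([1] * 5, dt_ps=500)
        assert st_.n_events == 1
        assert st_.longest_ns == 2.5

    def test_empty_series(self):
        st_ = contact_durations([0, 0, 0], dt_ps=1000)
        assert (st_.longest_ns, st_.mean_ns, st_.n_events) == (0.0, 0.0, 0)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ParameterError):
            contact_durations([1], dt_ps=0)

    @given(st.lists(st.booleans(), min_size=1, max_size=60),
           st.floats(min_value=10, max_value=5000))
    @settings(max_examples=60)
    def test_matches_rle_oracle(self, series, dt):
        expected = _rle_durations_oracle(series, dt)
        got = contact_durations(series, dt)
        np.testing.assert_allclose(sorted(got.events_ns), sorted(expected))
        assert got.n_events == len(expected)
        if expected:
            assert got.longest_ns == pytest.approx(max(expected))
            assert got.mean_ns == pytest.approx(sum(expected) / len(expected))
            assert got.longest_ns >= got.mean_ns


@pytest.fixture(scope="module")
def scripted_table():
    # residue 0 <- molecule 0 in frames {0,1,3}, molecule 1 in frame 1
    # residue 1 <- molecule 2 in frames {1,2}
    schedule = {(0, 0): {0, 1, 3}, (0, 1): {1}, (1, 2): {1, 2}}
    system = make_scripted_contact_system(schedule, n_frames=4, n_residues=2,
                                          n_molecules=3, dt_ps=1000.0)
    series = compute_contact_series(system, ContactParams(cutoff=0.7))
    return build_metrics_table(series, system), system, series


class TestMetricsTable:
    def test_hand_computed_values(self, scripted_table):
        table, _, _ = scripted_table
        r0 = table[(table["residue_id"] == 1) & (table["lipid_type"] == "POPC")].iloc[0]
        # frames with any contact: {0,1,3} -> occupancy 0.75
        assert r0["occupancy"] == 0.75
        # counts per frame: [1,2,0,1] -> mean 1.0, sum 4
        assert r0["mean_count"] == 1.0
        assert r0["sum_count"] == 4
        # molecule 0 events: {0,1} and {3} -> 2,1 ns; molecule 1: {1} -> 1 ns
        assert r0["longest_duration_ns"] == 2.0
        assert r0["mean_duration_ns"] == pytest.approx((2 + 1 + 1) / 3)
        assert r0["n_events"] == 3

        r1 = table[(table["residue_id"] == 2) & (table["lipid_type"] == "POPC")].iloc[0]
        assert r1["occupancy"] == 0.5
        assert r1["longest_duration_ns"] == 2.0
        assert r1["n_events"] == 1

    def test_sum_count_equals_mean_times_frames(self, scripted_table):
        table, _, series = scripted_table
        np.testing.assert_allclose(
            table["sum_count"], table["mean_count"] * series.n_frames
        )

    def test_zero_contact_rows_present_and_zero(self, scripted_table):
        table, _, _ = scripted_table
        # include_empty=True keeps rows for residues with no contacts
        zero = table[(table["occupancy"] == 0)]
        assert (zero[["mean_count", "sum_count", "longest_duration_ns",
                      "mean_duration_ns", "n_events"]].to_numpy() == 0).all()

    def test_occupancy_monotone_in_cutoff(self, membrane_system):
        small = build_metrics_table(
            compute_contact_series(membrane_system, ContactParams(cutoff=0.5)),
            membrane_system,
        )
        large = build_metrics_table(
            compute_contact_series(membrane_system, ContactParams(cutoff=0.8)),
            membrane_system,
        )
        key = ["residue_id", "lipid_type"]
        merged = small.merge(large, on=key, suffixes=("_s", "_l"))
        assert (merged["occupancy_s"] <= merged["occupancy_l"] + 1e-12).all()


class TestNetwork:
    def test_node_sizes_are_composition_fractions(self, membrane_system):
        series = compute_contact_series(membrane_system, ContactParams())
        table = build_metrics_table(series, membrane_system)
        payload = build_network(table, membrane_system)
        lipid_nodes = [n for n in payload["nodes"] if n["group"] == "lipid"]
        sizes = {n["id"]: n["size"] for n in lipid_nodes}
        assert sizes["POPC"] == pytest.approx(56 / 64)
        assert sizes["CHOL"] == pytest.approx(8 / 64)
        class_nodes = [n for n in payload["nodes"] if n["group"] == "residue_class"]
        assert sum(n["size"] for n in class_nodes) == pytest.approx(1.0)
        assert sum(n["size"] for n in lipid_nodes) == pytest.approx(1.0)

    def test_class_sizes_scale_to_residue_count(self, membrane_system):
        series = compute_contact_series(membrane_system, ContactParams())
        table = build_metrics_table(series, membrane_system)
        payload = build_network(table, membrane_system)
        n_prot = membrane_system.n_protein_residues
        total = sum(
            n["size"] * n_prot for n in payload["nodes"] if n["group"] == "residue_class"
        )
        assert total == pytest.approx(n_prot)

    def test_constant_metric_gives_constant_edges(self, scripted_table):
        table, system, _ = scripted_table
        t2 = table.copy()
        t2["mean_count"] = 3.0
        payload = build_network(t2, system, metric="mean_count")
        assert all(e["width"] == pytest.approx(3.0) for e in payload["links"])

    def test_expanded_class_lists_every_member_residue(self, membrane_system):
        series = compute_contact_series(membrane_system, ContactParams())
        table = build_metrics_table(series, membrane_system)
        payload = build_network(table, membrane_system, expand_class="positive")
        expanded = [n["id"] for n in payload["nodes"] if n["group"] == "residue"]
        expected = {
            f"{r.name}{r.resid}"
            for r in (membrane_system.residues[i]
                      for i in membrane_system.protein_residue_indices)
            if DEFAULT_RESIDUE_CLASSES.get(r.name) == "positive"
        }
        assert set(expanded) == expected
        assert expected  # fixture palette includes ARG and LYS

    def test_unknown_metric_rejected(self, scripted_table):
        table, system, _ = scripted_table
        with pytest.raises(ParameterError):
            build_network(table, system, metric="bogus")

    def test_networkx_conversion(self, membrane_system):
        from liprot.metrics import to_networkx

        series = compute_contact_series(membrane_system, ContactParams())
        table = build_metrics_table(series, membrane_system)
        payload = build_network(table, membrane_system)
        g = to_networkx(payload)
        assert g.number_of_nodes() == len(payload["nodes"])
        assert g.number_of_edges() == len(payload["links"])
        assert g.nodes["POPC"]["group"] == "lipid"

    def test_class_map_from_yaml(self, tmp_path, scripted_table):
        table, system, _ = scripted_table
        cfg = tmp_path / "classes.yaml"
        cfg.write_text("tiny: [ALA, GLY]\nbig: [TRP, TYR, PHE]\n")
        mapping = load_residue_classes(cfg)
        assert mapping["ALA"] == "tiny"
        payload = build_network(table, system, class_map=mapping)
        groups = {n["id"] for n in payload["nodes"] if n["group"] == "residue_class"}
        assert groups == {"tiny"}  # scripted system is all-ALA
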