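"""Contact detection: minimum-image distances, cell-list search, series."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liprot.contacts import (
    ContactParams,
    brute_force_pairs,
    compute_contact_series,
    min_image_distance,
    neighbor_pairs,
)
from liprot.errors import ParameterError
from liprot.fixtures import (
    make_scripted_contact_system,
    schedule_presence,
)
from liprot.io import FrameSet, Topology
from liprot.system import build_system


class TestMinImageDistance:
    @pytest.mark.parametrize(
        "p, q, box, expected",
        [
            ((0.1, 0, 0), (9.9, 0, 0), (10, 10, 10), 0.2),
            ((1, 1, 1), (1, 1, 1), (10, 10, 10), 0.0),
            ((1, 1, 1), (2, 2, 2), (100, 100, 100), math.sqrt(3)),
            ((0.5, 9.5, 5.0), (9.5, 0.5, 5.0), (10, 10, 10), math.sqrt(2)),
        ],
    )
    def test_examples(self, p, q, box, expected):
        assert min_image_distance(p, q, box) == pytest.approx(expected)

    def test_nonpositive_box_rejected(self):
        with pytest.raises(ParameterError):
            min_image_distance((0, 0, 0), (1, 1, 1), (10, 0, 10))


class TestNeighborPairs:
    def test_boundary_distance_is_included(self):
        coords = np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]])
        pairs = neighbor_pairs(coords, (10, 10, 10), [0], [1], cutoff=0.5)
        assert pairs == {(0, 1)}

    def test_empty_lipid_set(self):
        coords = np.ones((2, 3))
        assert neighbor_pairs(coords, (10, 10, 10), [0, 1], [], 0.5) == set()

    def test_cutoff_too_large_rejected(self):
        with pytest.raises(ParameterError, match="cutoff"):
            neighbor_pairs(np.ones((2, 3)), (2, 10, 10), [0], [1], cutoff=1.0)

    def test_wrap_across_boundary(self):
        coords = np.array([[0.05, 5.0, 5.0], [9.95, 5.0, 5.0]])
        assert neighbor_pairs(coords, (10, 10, 10), [0], [1], 0.2) == {(0, 1)}

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        box = rng.uniform(3.0, 8.0, size=3)
        n = int(rng.integers(20, 120))
        coords = rng.uniform(-5, 15, size=(n, 3))  # deliberately unwrapped
        na = n // 3
        idx_a = np.arange(na)
        idx_b = np.arange(na, n)
        cutoff = float(rng.uniform(0.2, min(box) / 2 - 0.05))
        assert neighbor_pairs(coords, box, idx_a, idx_b, cutoff) == brute_force_pairs(
            coords, box, idx_a, idx_b, cutoff
        )

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        box = np.array([6.0, 6.0, 6.0])
        coords = rng.uniform(0, 6, size=(60, 3))
        idx_a, idx_b = np.arange(20), np.arange(20, 60)
        small = neighbor_pairs(coords, box, idx_a, idx_b, 0.6)
        large = neighbor_pairs(coords, box, idx_a, idx_b, 1.2)
        assert small <= large


def _two_bead_system(lipid_xy, n_frames=1, box=(10.0, 10.0, 10.0)):
    """One ALA bead at the center plus one POPC bead per requested position."""
    n_lip = len(lipid_xy)
    names = ["BB"] + ["PO4"] * n_lip
    resids = list(range(1, n_lip + 2))
    resnames = ["ALA"] + ["POPC"] * n_lip
    coords = np.zeros((n_frames, n_lip + 1, 3))
    coords[:, 0] = (5.0, 5.0, 5.0)
    for i, xy in enumerate(lipid_xy):
        coords[:, i + 1] = xy
    topo = Topology.from_atom_records(names, resids, resnames)
    frames = FrameSet(coords, np.tile(np.asarray(box), (n_frames, 1)),
                      np.arange(n_frames) * 1000.0)
    return build_system(topo, frames)


class TestContactSeries:
    def test_scripted_schedule_recovered(self):
        schedule = {(5, 2): {0, 2}, (1, 0): {1, 2, 3}}
        system = make_scripted_contact_system(schedule, n_frames=4, n_residues=6,
                                              n_molecules=3)
        series = compute_contact_series(system, ContactParams(cutoff=0.7))
        expected = schedule_presence(schedule, 6, 3, 4)
        np.testing.assert_array_equal(series.presence["POPC"], expected)
        np.testing.assert_array_equal(series.presence["POPC"][5, 2], [1, 0, 1, 0])

    def test_vanishing_cutoff_gives_empty_series(self):
        schedule = {(0, 0): {0, 1}}
        system = make_scripted_contact_system(schedule, n_frames=2)
        series = compute_contact_series(system, ContactParams(cutoff=0.001))
        assert not series.presence["POPC"].any()

    def test_headgroup_selection_excludes_tail_approach(self):
        # tail bead C4A at 0.5 nm from the residue, headgroup PO4 3 nm away
        names = ["BB", "PO4", "C4A"]
        resids = [1, 2, 2]
        resnames = ["ALA", "POPC", "POPC"]
        coords = np.zeros((1, 3, 3))
        coords[0, 0] = (5.0, 5.0, 5.0)
        coords[0, 1] = (8.0, 5.0, 5.0)  # headgroup far
        coords[0, 2] = (5.5, 5.0, 5.0)  # tail close
        topo = Topology.from_atom_records(names, resids, resnames)
        frames = FrameSet(coords, np.full((1, 3), 12.0), np.zeros(1))
        system = build_system(topo, frames)
        all_beads = compute_contact_series(system, ContactParams(cutoff=0.7))
        head_only = compute_contact_series(
            system, ContactParams(cutoff=0.7, lipid_selection="headgroup")
        )
        assert all_beads.presence["POPC"].any()
        assert not head_only.presence["POPC"].any()

    def test_counts_equal_distinct_molecules(self):
        system = _two_bead_system([(5.5, 5.0, 5.0), (4.5, 5.0, 5.0), (9.0, 9.0, 9.0)])
        series = compute_contact_series(system, ContactParams(cutoff=0.7))
        assert series.counts("POPC")[0, 0] == 2

    def test_translation_invariance_mod_box(self):
        schedule = {(0, 0): {0, 2}, (2, 1): {1}}
        system = make_scripted_contact_system(schedule, n_frames=3, n_residues=3,
                                              n_molecules=2)
        base = compute_contact_series(system, ContactParams(cutoff=0.7))
        shift = np.array([1.7, -2.3, 0.9])
        system.frames.coordinates += shift  # wrapping happens inside the search
        shifted = compute_contact_series(system, ContactParams(cutoff=0.7))
        for t in base.presence:
            np.testing.assert_array_equal(base.presence[t], shifted.presence[t])

    def test_cutoff_monotonicity_of_presence(self, membrane_system):
        small = compute_contact_series(membrane_system, ContactParams(cutoff=0.5))
        large = compute_contact_series(membrane_system, ContactParams(cutoff=0.8))
        for t in small.presence:
            assert not (small.presence[t] & ~large.presence[t]).any()

    def test_stride_honored(self):
        schedule = {(0, 0): {0, 1, 2, 3}}
        system = make_scripted_contact_system(schedule, n_frames=4)
        series = compute_contact_series(system, ContactParams(stride=2))
        assert series.n_frames == 2

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            ContactParams(cutoff=0.0)
        with pytest.raises(ParameterError):
            ContactParams(stride=0)

    def test_serialization_round_trip(self, tmp_path):
        schedule = {(1, 0): {0, 3}, (0, 1): {2}}
        system = make_scripted_contact_system(schedule, n_frames=4, n_residues=2,
                                              n_molecules=2)
        series = compute_contact_series(system)
        df = series.to_dataframe()
        assert len(df) == 3
        assert set(df.columns) == {
            "residue_id", "lipid_type", "lipid_mol_id", "frame", "time_ps", "in_contact"
        }
        series.save(tmp_path / "c.csv.gz")
        import pandas as pd

        back = pd.read_csv(tmp_path / "c.csv.gz", comment="#")
        assert len(back) == 3
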