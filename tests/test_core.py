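import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scwforge.core import (
    ParseError,
    Selection,
    Structure,
    min_image_distance,
    read_frames,
    read_structure,
    write_frames,
    write_structure,
)


def brute_min_image(a, b, box):
    """27-image oracle."""
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                shift = np.array([i, j, k]) * box
                best = min(best, np.linalg.norm(np.asarray(b) + shift - np.asarray(a)))
    return best


class TestMinImage:
    def test_identical_points(self):
        assert min_image_distance([1, 2, 3], [1, 2, 3], [10, 10, 10]) == 0.0

    def test_wrap_by_one_period(self):
        d = min_image_distance([0, 0, 0], [19, 0, 0], [20, 20, 20])
        assert d == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 30, (2, 3))
        box = np.array([17.0, 23.0, 31.0])
        assert min_image_distance(a, b, box) == pytest.approx(
            min_image_distance(b, a, box)
        )

    def test_invariant_to_integer_box_shifts(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 30, (2, 3))
        box = np.array([17.0, 23.0, 31.0])
        d0 = min_image_distance(a, b, box)
        assert min_image_distance(a, b + np.array([3, -2, 5]) * box, box) == pytest.approx(d0)

    def test_against_27_image_oracle(self):
        # the 27-image oracle is exact once both points sit in the primary
        # cell; arbitrary points are first wrapped (distance is invariant)
        rng = np.random.default_rng(42)
        box = np.array([15.0, 21.0, 27.0])
        for _ in range(1000):
            a = np.mod(rng.uniform(-40, 70, 3), box)
            b = np.mod(rng.uniform(-40, 70, 3), box)
            assert min_image_distance(a, b, box) == pytest.approx(
                brute_min_image(a, b, box), abs=1e-9
            )

    def test_upper_bound(self):
        rng = np.random.default_rng(3)
        box = np.array([10.0, 12.0, 14.0])
        cap = np.linalg.norm(box / 2)
        for _ in range(200):
            d = min_image_distance(rng.uniform(0, 50, 3), rng.uniform(0, 50, 3), box)
            assert 0.0 <= d <= cap + 1e-12

    def test_nonpositive_box_raises(self):
        with pytest.raises(ValueError):
            min_image_distance([0, 0, 0], [1, 1, 1], [10, -1, 10])

    @given(
        a=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
        b=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
        box=st.tuples(*[st.floats(201, 400) for _ in range(3)]),
    )
    @settings(max_examples=200, deadline=None)
    def test_property_large_box_equals_euclidean(self, a, b, box):
        # box exceeds twice the coordinate spread -> plain distance
        d = min_image_distance(np.array(a), np.array(b), np.array(box))
        assert d == pytest.approx(np.linalg.norm(np.array(b) - np.array(a)), abs=1e-9)


class TestStructureIO:
    def test_empty_roundtrip(self, tmp_path):
        p = tmp_path / "empty.pdb"
        write_structure(Structure.empty(), p)
        s = read_structure(p)
        assert s.n_atoms == 0

    def test_fibril_roundtrip(self, small_fibril, tmp_path):
        p = tmp_path / "fib.pdb"
        write_structure(small_fibril, p)
        s = read_structure(p)
        assert s.n_atoms == small_fibril.n_atoms
        assert list(s.atom_label) == list(small_fibril.atom_label)
        assert np.allclose(s.positions, small_fibril.positions, atol=1e-3)
        assert list(s.polymer_class) == list(small_fibril.polymer_class)

    def test_cryst1_box(self, tmp_path):
        p = tmp_path / "t.pdb"
        p.write_text(
            "CRYST1   20.000   20.000   20.000  90.00  90.00  90.00 P 1           1\n"
            "ATOM      1  C1  GLC C   1       1.000   2.000   3.000  1.00  0.00      C000 C\n"
            "ATOM      2  C2  GLC C   1       2.000   2.000   3.000  1.00  0.00      C000 C\n"
            "ATOM      3  O2  GLC C   1       2.000   3.000   3.000  1.00  0.00      C000 O\n"
            "END\n"
        )
        s = read_structure(p)
        assert s.periodic
        assert np.allclose(s.box, [20, 20, 20])
        assert s.n_atoms == 3

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  C1  GLC C   1      xxxxxx   2.000   3.000\n")
        with pytest.raises(ParseError, match="bad.pdb:1"):
            read_structure(p)

    def test_xyz_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        n = 20
        s = Structure(
            rng.uniform(0, 10, (n, 3)), ["C"] * n, ["C1"] * n,
            np.arange(n), ["GLC"] * n, np.zeros(n, int), ["cellulose"] * n,
            box=[30, 30, 30], periodic=True,
        )
        p = tmp_path / "t.xyz"
        write_structure(s, p)
        s2 = read_structure(p)
        assert s2.n_atoms == n
        assert np.allclose(s2.positions, s.positions, atol=1e-3)
        assert np.allclose(s2.box, s.box)

    def test_multimodel_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        n = 8
        frames = []
        for _ in range(3):
            frames.append(
                Structure(
                    rng.uniform(0, 10, (n, 3)), ["C"] * n, ["C1"] * n,
                    np.arange(n), ["GLC"] * n, np.zeros(n, int), ["cellulose"] * n,
                    box=[30, 30, 30], periodic=True,
                )
            )
        p = tmp_path / "frames.pdb"
        write_frames(frames, p)
        back = read_frames(p)
        assert len(back) == 3
        for a, b in zip(frames, back):
            assert np.allclose(a.positions, b.positions, atol=1e-3)


class TestStructure:
    def test_wrap_preserves_min_image_distances(self, xylan_twofold):
        s = xylan_twofold.copy()
        s.box = np.array([60.0, 60.0, 250.0])
        s.periodic = True
        w = s.wrapped()
        rng = np.random.default_rng(0)
        idx = rng.choice(s.n_atoms, 40, replace=False)
        for i, j in zip(idx[::2], idx[1::2]):
            d0 = min_image_distance(s.positions[i], s.positions[j], s.box)
            d1 = min_image_distance(w.positions[i], w.positions[j], s.box)
            assert d0 == pytest.approx(d1, abs=1e-9)

    def test_selection_reproducible_and_ordered(self, xylan_twofold):
        sel = Selection(polymer_class="xylan", atom_labels=frozenset({"AcMe"}))
        ids1 = sel.resolve(xylan_twofold)
        ids2 = sel.resolve(xylan_twofold)
        assert np.array_equal(ids1, ids2)
        assert np.all(np.diff(ids1) > 0)

    def test_inconsistent_class_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            Structure(
                [[0, 0, 0]], ["C"], ["C1"], [1], ["GLC"], [0], ["lignin"]
            ).validate()

    def test_periodic_requires_box(self):
        with pytest.raises(ValueError):
            Structure.empty(periodic=True)

    def test_mass_water(self):
        s = Structure(
            [[0, 0, 0]], ["O"], ["OW"], [1], ["WAT"], [0], ["water"]
        )
        assert s.mass() == pytest.approx(18.015, abs=0.01)
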