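import numpy as np
import pytest

from conftest import random_periodic_structure
from scwforge.builders import LigninSpec, XylanSpec, build_lignin, build_xylan
from scwforge.core import Structure
from scwforge.proximity import (
    EXPERIMENTAL_REFERENCE,
    percent_within,
    percent_within_bruteforce,
    proximity_profile,
    select_atoms,
)


class TestSelectAtoms:
    def test_xylan_acme_count(self, xylan_twofold):
        assert len(select_atoms(xylan_twofold, "xylan_AcMe")) == 20

    def test_lignin_ring_count(self, lignin_default):
        s, _ = lignin_default
        # 2 ring carbons per monomer: 13*2 + 7*2
        assert len(select_atoms(s, "lignin_ring")) == 40

    def test_empty_selection_warns(self, xylan_twofold):
        with pytest.warns(UserWarning, match="no atoms"):
            ids = select_atoms(xylan_twofold, "lignin_ring")
        assert len(ids) == 0

    def test_sink_class_carbons_only(self, xylan_twofold):
        ids = select_atoms(xylan_twofold, "xylan")
        assert all(e == "C" for e in xylan_twofold.element[ids])


class TestPercentWithin:
    def test_coincident_sinks_100(self):
        n = 30
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 20, (n, 3))
        s = Structure(pos, ["C"] * n, ["C1"] * n, np.arange(n), ["GLC"] * n,
                      np.zeros(n, int), ["cellulose"] * n,
                      box=[50, 50, 50], periodic=True)
        r = percent_within(s, np.arange(n), np.arange(n), 10.0)
        assert r.percent == 100.0

    def test_all_far_zero(self):
        pos = np.array([[0, 0, 0], [60, 60, 60]], dtype=float)
        s = Structure(pos, ["C", "C"], ["C1", "C1"], [1, 2], ["GLC"] * 2,
                      [0, 0], ["cellulose"] * 2, box=[130, 130, 130], periodic=True)
        r = percent_within(s, np.array([0]), np.array([1]), 10.0)
        assert r.percent == 0.0

    def test_cutoff_exceeding_half_box_raises(self):
        s = Structure([[0, 0, 0]], ["C"], ["C1"], [1], ["GLC"], [0],
                      ["cellulose"], box=[15, 50, 50], periodic=True)
        with pytest.raises(ValueError, match="half the smallest box"):
            percent_within(s, np.array([0]), np.array([0]), 10.0)

    def test_equals_bruteforce_on_random_systems(self):
        rng = np.random.default_rng(7)
        for trial in range(50):
            n = int(rng.integers(100, 2001))
            box = rng.uniform(25, 70, 3)
            s = random_periodic_structure(rng, n, box)
            src = rng.choice(n, min(50, n // 2), replace=False)
            snk = np.arange(n)
            cutoff = float(rng.uniform(3.0, min(box) / 2 - 0.1))
            a = percent_within(s, src, snk, cutoff)
            b = percent_within_bruteforce(s, src, snk, cutoff)
            assert a.n_sink_within == b.n_sink_within, f"trial {trial}"

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(11)
        s = random_periodic_structure(rng, 500, [40, 45, 50])
        src = rng.choice(500, 30, replace=False)
        snk = np.arange(500)
        percents = [
            percent_within(s, src, snk, c).percent for c in (4.0, 7.0, 10.0, 13.0, 16.0)
        ]
        assert all(a <= b for a, b in zip(percents, percents[1:]))

    def test_translation_invariance(self):
        rng = np.random.default_rng(13)
        s = random_periodic_structure(rng, 400, [40, 40, 40])
        src = rng.choice(400, 25, replace=False)
        snk = np.arange(400)
        base = percent_within(s, src, snk, 9.0).percent
        for shift in ([13.0, -7.0, 29.0], [100.0, 0.1, -55.0]):
            t = s.translate(shift)
            assert percent_within(t, src, snk, 9.0).percent == base


class TestProximityProfile:
    def _toy_sandwich(self, gap):
        """One short xylan chain between a minimal cellulose chain and a
        lignin monomer, centroids spaced by ``gap`` along x."""
        from scwforge.builders import FibrilSpec, build_cellulose_fibril

        cel = build_cellulose_fibril(FibrilSpec(n_chains=1, arrangement=(1,), dp=1))
        xyl = build_xylan(XylanSpec(dp=2))
        lig, _ = build_lignin(
            LigninSpec(n_monomers=1, n_syringyl=1, n_guaiacyl=0,
                       linkage_fractions=(("beta-O-4", 1.0),)),
            seed=0,
        )
        cel = cel.translate(-cel.positions.mean(axis=0))
        xyl = xyl.translate([gap, 0, 0] - xyl.positions.mean(axis=0))
        # centre the lignin between the acetyl methyl (the single source)
        # and the xylan centroid so both see the whole monomer
        acme = xyl.positions[xyl.atom_label == "AcMe"][0]
        mid = 0.5 * (acme + xyl.positions.mean(axis=0))
        lig = lig.translate(mid + [gap, 0.0, 0.0] - lig.positions.mean(axis=0))
        parts = [cel, xyl, lig]
        span = 3 * gap + 60.0
        s = Structure.concat(parts, box=[span, 60.0, 60.0], periodic=True)
        s.positions += np.array([span / 2, 30.0, 30.0])
        return s

    def test_tight_sandwich_all_100(self):
        s = self._toy_sandwich(gap=3.0)
        for r in proximity_profile(s, cutoff=10.0):
            assert r.percent == 100.0

    def test_separated_pairs_zero(self):
        s = self._toy_sandwich(gap=25.0)
        res = {(r.source_label, r.sink_class): r.percent for r in proximity_profile(s)}
        assert res[("xylan_AcMe", "lignin")] < 100.0
        # cellulose and lignin are 50 A apart
        assert res[("lignin_ring", "cellulose")] == 0.0

    def test_monotone_profile_sweep(self, toy_models):
        s, _ = toy_models["a"]
        p10 = {(r.source_label, r.sink_class): r.percent
               for r in proximity_profile(s, cutoff=10.0)}
        p12 = {(r.source_label, r.sink_class): r.percent
               for r in proximity_profile(s, cutoff=12.0)}
        for k in p10:
            assert p12[k] >= p10[k]

    def test_reference_values(self):
        assert EXPERIMENTAL_REFERENCE[("xylan_AcMe", "lignin")] == 80.0
        assert EXPERIMENTAL_REFERENCE[("xylan_AcMe", "cellulose")] == 40.0
        assert EXPERIMENTAL_REFERENCE[("lignin_ring", "xylan")] == 60.0
        assert EXPERIMENTAL_REFERENCE[("lignin_ring", "cellulose")] == 20.0


class TestAsymmetry:
    def test_trapped_xylan_asymmetry(self, toy_trapped):
        """Trapped-xylan toys separate the two cross-polymer metrics."""
        s, rep = toy_trapped
        assert rep.placement_counts("xylan").get("trapped", 0) >= 1
        res = {(r.source_label, r.sink_class): r.percent for r in proximity_profile(s)}
        assert res[("xylan_AcMe", "lignin")] < res[("lignin_ring", "xylan")]
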