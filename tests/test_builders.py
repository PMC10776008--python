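import numpy as np
import pytest
from scipy.spatial import cKDTree

from scwforge.builders import (
    DEFAULT_LINKAGE_FRACTIONS,
    FibrilSpec,
    LigninSpec,
    XylanSpec,
    build_cellulose_fibril,
    build_lignin,
    build_lignin_ensemble,
    build_xylan,
    lignin_contour_length,
)
from scwforge.conformation import theta_2f


def glycosidic_bonds(s):
    """All C1(i+1)-O4(i) bond lengths along sugar backbones."""
    res = {}
    for cid, rix, rtype, idx in s.residues():
        if rtype in ("GLC", "XYL"):
            res[(cid, rix)] = {
                str(s.atom_label[i]): s.positions[i] for i in idx
            }
    out = []
    for (cid, rix), d in res.items():
        nxt = res.get((cid, rix + 1))
        if nxt is not None:
            out.append(np.linalg.norm(nxt["C1"] - d["O4"]))
    return np.asarray(out)


class TestFibril:
    def test_default_has_18_chains(self, default_fibril):
        assert len(np.unique(default_fibril.chain_id)) == 18

    def test_default_residue_count(self, default_fibril):
        # 18 chains x DP 40
        n_res = sum(1 for _ in default_fibril.residues())
        assert n_res == 720

    def test_single_glucose(self):
        s = build_cellulose_fibril(FibrilSpec(n_chains=1, arrangement=(1,), dp=1))
        assert sum(1 for _ in s.residues()) == 1
        assert len(glycosidic_bonds(s)) == 0

    def test_arrangement_mismatch_raises(self):
        with pytest.raises(ValueError, match="arrangement"):
            FibrilSpec(n_chains=18, arrangement=(2, 3, 4))

    def test_glycosidic_bond_lengths(self, default_fibril):
        b = glycosidic_bonds(default_fibril)
        assert len(b) == 18 * 39
        assert b.min() > 1.3 and b.max() < 1.5

    def test_no_nonbonded_clashes(self, default_fibril):
        s = default_fibril
        tree = cKDTree(s.positions)
        pairs = tree.query_pairs(1.8, output_type="ndarray")
        for i, j in pairs:
            same_chain = s.chain_id[i] == s.chain_id[j]
            adjacent = same_chain and abs(int(s.residue_index[i]) - int(s.residue_index[j])) <= 1
            assert adjacent, (
                f"non-bonded contact {s.atom_label[i]}-{s.atom_label[j]} at "
                f"{np.linalg.norm(s.positions[i] - s.positions[j]):.2f} A"
            )

    def test_chains_parallel(self, small_fibril):
        # per-chain end-to-end vectors should all point along +-z
        for cid, idx in small_fibril.chain_atom_indices().items():
            pos = small_fibril.positions[idx]
            v = pos[np.argmax(pos[:, 2])] - pos[np.argmin(pos[:, 2])]
            v = v / np.linalg.norm(v)
            assert abs(v[2]) > 0.99


class TestXylan:
    def test_default_acetyl_count(self, xylan_twofold):
        # every other residue of 40 carries one acetyl
        n_ace = sum(1 for _, _, rt, _ in xylan_twofold.residues() if rt == "ACE")
        assert n_ace == 20

    @pytest.mark.parametrize("phase,expected", [(2, 5), (4, 5), (6, 5), (8, 5)])
    def test_glca_counts_by_phase(self, phase, expected):
        s = build_xylan(XylanSpec(glca_phase=phase))
        n = sum(1 for _, _, rt, _ in s.residues() if rt == "GLCA")
        # residues phase, phase+8, ... <= 40
        assert n == len(range(phase, 41, 8)) == expected

    def test_dp2_single_acetyl(self):
        s = build_xylan(XylanSpec(dp=2))
        assert sum(1 for _, _, rt, _ in s.residues() if rt == "ACE") == 1

    def test_odd_glca_phase_rejected(self):
        with pytest.raises(ValueError, match="even"):
            XylanSpec(glca_phase=3)

    def test_glca_residue_carries_o3_acetyl(self):
        """Residues whose O2 holds GlcA still carry an acetyl (on O3)."""
        s = build_xylan(XylanSpec())
        n_ace = sum(1 for _, _, rt, _ in s.residues() if rt == "ACE")
        assert n_ace == 20  # none lost to GlcA displacement

    def test_twofold_theta2f_near_zero(self, xylan_twofold):
        series = theta_2f(xylan_twofold, 0)
        assert len(series.values) == 19
        assert all(abs(v) <= 15.0 for v in series.values)

    def test_backbone_bond_lengths(self, xylan_twofold):
        b = glycosidic_bonds(xylan_twofold)
        assert b.min() > 1.3 and b.max() < 1.5


class TestLignin:
    def test_composition(self, lignin_default):
        s, links = lignin_default
        kinds = [rt for _, _, rt, _ in s.residues()]
        assert kinds.count("SYR") == 13
        assert kinds.count("GUA") == 7
        assert len(links) == 19

    def test_dimer_single_beta_o4(self):
        spec = LigninSpec(
            n_monomers=2, n_syringyl=1, n_guaiacyl=1,
            linkage_fractions=(("beta-O-4", 1.0),),
        )
        _s, links = build_lignin(spec, seed=0)
        assert [l["type"] for l in links] == ["beta-O-4"]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            LigninSpec(linkage_fractions=(("beta-O-4", 0.5),))

    def test_seed_determinism(self):
        a, la = build_lignin(LigninSpec(), seed=9)
        b, lb = build_lignin(LigninSpec(), seed=9)
        assert np.array_equal(a.positions, b.positions)
        assert la == lb

    def test_extended_end_to_end(self):
        s, _ = build_lignin(LigninSpec(shape="extended"), seed=2)
        c1 = s.positions[s.residue_index == 1].mean(axis=0)
        c20 = s.positions[s.residue_index == 20].mean(axis=0)
        assert np.linalg.norm(c20 - c1) > 0.8 * lignin_contour_length()

    def test_globular_radius_of_gyration(self):
        ext, _ = build_lignin(LigninSpec(shape="extended"), seed=2)
        c1 = ext.positions[ext.residue_index == 1].mean(axis=0)
        c20 = ext.positions[ext.residue_index == 20].mean(axis=0)
        e2e = np.linalg.norm(c20 - c1)
        glob, _ = build_lignin(LigninSpec(shape="globular"), seed=2)
        x = glob.positions
        rg = np.sqrt(((x - x.mean(axis=0)) ** 2).sum(axis=1).mean())
        assert rg < 0.3 * e2e

    def test_ensemble_beta_o4_exact(self):
        ens = build_lignin_ensemble(LigninSpec(), 20, seed=4)
        types = [l["type"] for _s, links in ens for l in links]
        frac = types.count("beta-O-4") / len(types)
        assert frac == pytest.approx(DEFAULT_LINKAGE_FRACTIONS["beta-O-4"], abs=1e-12)

    def test_ensemble_within_two_points_smaller(self):
        # chain counts not divisible by 5 still land within 2 points of 80%
        ens = build_lignin_ensemble(LigninSpec(), 7, seed=4)
        types = [l["type"] for _s, links in ens for l in links]
        frac = types.count("beta-O-4") / len(types)
        assert abs(frac - 0.80) < 0.02
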