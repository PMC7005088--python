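import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axoporate.membrane_synth import (
    INNER_DEFAULT,
    OUTER_DEFAULT,
    LeafletComposition,
    MembraneError,
    apply_strain,
    build_membrane,
    largest_remainder,
    plant_interdigitation,
    plant_pore,
    set_core_water,
    embed_protein,
    synth_tension_series,
)


def oracle_largest_remainder(fractions, total):
    """Independent reimplementation: floor everything, then hand out the
    leftover seats one by one to the largest fractional parts."""
    items = sorted(fractions.items())
    quotas = [(k, f * total) for k, f in items]
    counts = {k: int(q) for k, q in quotas}
    leftover = total - sum(counts.values())
    by_frac = sorted(quotas, key=lambda kv: (kv[1] - int(kv[1])), reverse=True)
    i = 0
    while leftover > 0:
        counts[by_frac[i][0]] += 1
        leftover -= 1
        i += 1
    return counts


class TestLeafletComposition:
    def test_defaults_sum_to_one(self):
        comp = LeafletComposition()
        assert sum(comp.outer.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(comp.inner.values()) == pytest.approx(1.0, abs=1e-12)

    def test_printed_fractions(self):
        assert OUTER_DEFAULT["CHOL"] == 0.31
        assert OUTER_DEFAULT["PC"] == 0.36
        assert INNER_DEFAULT["PS"] == 0.11

    def test_bad_sum_rejected(self):
        with pytest.raises(MembraneError):
            LeafletComposition(outer={"PC": 0.9}, inner=INNER_DEFAULT)


class TestLargestRemainder:
    def test_exact_fractions(self):
        counts = largest_remainder({"a": 0.5, "b": 0.5}, 10)
        assert counts == {"a": 5, "b": 5}

    @given(total=st.integers(1, 500),
           weights=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_and_sums(self, total, weights):
        w = np.array(weights)
        fr = {f"s{i}": v for i, v in enumerate(w / w.sum())}
        counts = largest_remainder(fr, total)
        assert sum(counts.values()) == total
        assert counts == oracle_largest_remainder(fr, total)
        for k, c in counts.items():
            assert abs(c - fr[k] * total) <= 1.0


class TestBuildMembrane:
    def test_total_lipid_count_small(self, small_membrane):
        assert small_membrane.n_lipids == 670

    def test_leaflet_fractions_sum_to_one(self, small_membrane):
        for leaf in ("outer", "inner"):
            assert sum(small_membrane.leaflet_fractions(leaf).values()) \
                == pytest.approx(1.0)

    def test_outer_chol_fraction_within_rounding(self, small_membrane):
        fr = small_membrane.leaflet_fractions("outer")
        n_leaf = 335
        assert abs(fr["CHOL"] - 0.31) <= 1.0 / n_leaf

    def test_species_counts_match_largest_remainder_oracle(self, small_membrane):
        heads = small_membrane.select(kind="head", leaflet="outer")
        sp, counts = np.unique(small_membrane.species[heads], return_counts=True)
        got = dict(zip(sp.tolist(), counts.tolist()))
        assert got == oracle_largest_remainder(OUTER_DEFAULT, 335)

    def test_each_lipid_has_head_and_tails(self, small_membrane):
        m = small_membrane
        for lid in (0, 100, 669):
            beads = m.lipid_id == lid
            kinds = set(m.kind[beads].tolist())
            assert kinds == {"head", "tail"}

    def test_leaflet_geometry_consistent(self, small_membrane):
        m = small_membrane
        z0 = m.midplane
        outer = m.select(leaflet="outer")
        inner = m.select(leaflet="inner")
        assert np.all(m.coords[outer, 2] > z0)
        assert np.all(m.coords[inner, 2] < z0)

    def test_coords_inside_box(self, small_membrane):
        m = small_membrane
        assert np.all(m.coords >= 0)
        assert np.all(m.coords <= m.box + 1e-9)

    def test_seeded_determinism(self):
        a = build_membrane(n_lipids=100, hydration_beads=500, seed=3)
        b = build_membrane(n_lipids=100, hydration_beads=500, seed=3)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.species, b.species)

    def test_fraction_scale_invariance(self):
        small = build_membrane(n_lipids=670, hydration_beads=100, seed=1)
        tiny = build_membrane(n_lipids=67, hydration_beads=100, seed=1)
        fs = small.leaflet_fractions("outer")
        ft = tiny.leaflet_fractions("outer")
        for k in ft:
            assert abs(fs.get(k, 0) - ft[k]) < 0.05

    def test_box_too_small_rejected(self):
        with pytest.raises(MembraneError):
            build_membrane(box=(5.0, 5.0, 12.0), n_lipids=1000,
                           hydration_beads=100)

    def test_ion_count_matches_molarity(self, small_membrane):
        # 150 mM over the solvent volume, both species counted
        n_ion = int(small_membrane.select(kind="ion").sum())
        assert n_ion > 0
        z0 = small_membrane.midplane
        area = small_membrane.box[0] * small_membrane.box[1]
        slab = small_membrane.box[2] - 2 * (2.0 + 0.2)
        expected = 2 * 0.150 * 6.02214076e23 * area * slab * 1e-24
        assert n_ion == pytest.approx(expected, rel=0.01)


class TestEmbedProtein:
    def test_channel_density_arithmetic(self, small_membrane):
        cfg = embed_protein(small_membrane, footprint_radius=1.5)
        area_um2 = (cfg.box[0] * 1e-3) * (cfg.box[1] * 1e-3)
        assert round(1.0 / area_um2) == 567

    def test_zero_radius_noop(self, small_membrane):
        cfg = embed_protein(small_membrane, footprint_radius=0.0)
        assert cfg.n_beads == small_membrane.n_beads
        assert cfg.protein["volume"] == 0.0

    def test_removed_lipids_match_bruteforce_scan(self, small_membrane):
        r = 2.0
        cfg = embed_protein(small_membrane, footprint_radius=r)
        m = small_membrane
        center = np.array([m.box[0] / 2, m.box[1] / 2])
        heads = m.select(kind="head")
        d = m.coords[heads, :2] - center
        d = np.abs(d)
        d = np.minimum(d, m.box[:2] - d)
        inside = np.hypot(d[:, 0], d[:, 1]) <= r
        expected = len(np.unique(m.lipid_id[heads][inside]))
        assert cfg.metadata["protein_removed_lipids"] == expected
        assert cfg.n_lipids == m.n_lipids - expected

    def test_footprint_larger_than_box_rejected(self, small_membrane):
        with pytest.raises(MembraneError):
            embed_protein(small_membrane, footprint_radius=50.0)


class TestPlantPore:
    def test_zero_radius_noop(self, small_membrane):
        cfg = plant_pore(small_membrane, 0.0)
        assert cfg.n_beads == small_membrane.n_beads

    def test_column_crosses_midplane(self, small_membrane):
        cfg = plant_pore(small_membrane, 2.0)
        z0 = cfg.midplane
        col = cfg.coords[cfg.n_beads - cfg.metadata["pore"]["column_beads"]:]
        assert col[:, 2].min() < z0 - 1.5
        assert col[:, 2].max() > z0 + 1.5
        assert np.any(np.abs(col[:, 2] - z0) < 0.5)

    def test_too_large_rejected(self, small_membrane):
        with pytest.raises(MembraneError):
            plant_pore(small_membrane, 30.0)


class TestPlantInterdigitation:
    def test_zero_depth_noop(self, small_membrane):
        cfg = plant_interdigitation(small_membrane, 0.0)
        assert np.array_equal(cfg.coords, small_membrane.coords)

    def test_tails_move_toward_midplane(self, small_membrane):
        depth = 1.0
        cfg = plant_interdigitation(small_membrane, depth)
        m_out = small_membrane.select(kind="tail", leaflet="outer")
        shift = small_membrane.coords[m_out, 2] - cfg.coords[m_out, 2]
        assert np.all(shift >= -1e-12)
        assert np.all(shift <= depth + 1e-12)
        # the deepest beads travel (almost) the full depth
        assert shift.max() == pytest.approx(depth, abs=0.02)

    def test_invalid_depth_rejected(self, small_membrane):
        with pytest.raises(MembraneError):
            plant_interdigitation(small_membrane, 5.0)


class TestSetCoreWater:
    def test_planted_counts(self, small_membrane):
        cfg = set_core_water(small_membrane, -1.0, seed=2)
        assert cfg.metadata["core_water_beads"] > 0
        assert cfg.n_beads == small_membrane.n_beads  # beads moved, not added

    def test_unreachable_target_rejected(self, small_membrane):
        with pytest.raises(MembraneError):
            set_core_water(small_membrane, 3.0)


class TestApplyStrain:
    def test_identity(self, small_membrane):
        cfg = apply_strain(small_membrane, 0.0, 0.0)
        assert np.allclose(cfg.coords, small_membrane.coords)
        assert np.allclose(cfg.box, small_membrane.box)

    def test_fig5_strain_level(self, small_membrane):
        cfg = apply_strain(small_membrane, 0.34, 0.0)
        assert cfg.box[0] == pytest.approx(42.0 * 1.34)
        assert cfg.box[1] == pytest.approx(42.0)
        assert cfg.metadata["areal_strain"] == pytest.approx(0.34)

    def test_pairwise_distances_scale_affinely(self, small_membrane):
        ex, ey = 0.2, 0.1
        cfg = apply_strain(small_membrane, ex, ey)
        a = small_membrane.coords[:50]
        b = cfg.coords[:50]
        assert np.allclose(b[:, 0], a[:, 0] * (1 + ex))
        assert np.allclose(b[:, 1], a[:, 1] * (1 + ey))
        assert np.allclose(b[:, 2], a[:, 2])

    def test_invalid_strain_rejected(self, small_membrane):
        with pytest.raises(MembraneError):
            apply_strain(small_membrane, -1.5)


class TestSynthTensionSeries:
    def test_noiseless_linear_law(self):
        s = synth_tension_series(303.0, np.full(10, 0.02), noise_sd=0.0)
        assert np.allclose(s.gamma, 6.06)

    def test_noiseless_exactly_linear(self):
        eps = np.linspace(0, 0.05, 100)
        s = synth_tension_series(303.0, eps, noise_sd=0.0)
        assert np.allclose(s.gamma, 303.0 * eps)

    def test_planted_drop_recorded(self):
        eps = np.full(1000, 0.02)
        s = synth_tension_series(303.0, eps, noise_sd=0.0, pore_step=500,
                                 post_pore_drop=3.0)
        assert s.metadata["pore_step"] == 500
        assert s.gamma[499] - s.gamma[500] == pytest.approx(3.0)

    def test_invalid_modulus_rejected(self):
        with pytest.raises(MembraneError):
            synth_tension_series(0.0, np.zeros(10))

    def test_steps_strictly_increasing(self):
        s = synth_tension_series(100.0, np.zeros(50))
        assert np.all(np.diff(s.steps) > 0)
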