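import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axoporate.membrane_metrics import (
    detect_pore_geometric,
    detect_tension_jump,
    fit_area_compressibility,
    interdigitation_index,
    partition_coefficient,
    permeability_change,
)
from axoporate.membrane_synth import (
    BeadConfiguration,
    MembraneError,
    TensionSeries,
    build_membrane,
    plant_interdigitation,
    plant_pore,
    set_core_water,
    synth_tension_series,
)


def make_config(coords, kinds, leaflets=None, box=(10.0, 10.0, 10.0)):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    kinds = np.asarray(kinds, dtype=object)
    if leaflets is None:
        leaflets = np.full(n, "none", dtype=object)
    return BeadConfiguration(
        coords=coords, kind=kinds,
        leaflet=np.asarray(leaflets, dtype=object),
        species=np.full(n, "X", dtype=object),
        lipid_id=np.where(np.isin(kinds, ("head", "tail")),
                          np.arange(n), -1),
        box=np.asarray(box, dtype=float))


class TestFitAreaCompressibility:
    def test_noiseless_recovers_planted_modulus(self):
        eps = np.linspace(0.001, 0.049, 50)
        fit = fit_area_compressibility(list(zip(eps, 303.0 * eps)))
        assert fit.K_A == pytest.approx(303.0)
        assert fit.se == pytest.approx(0.0, abs=1e-9)

    def test_zero_tension_zero_modulus(self):
        eps = np.linspace(0.001, 0.049, 20)
        fit = fit_area_compressibility(list(zip(eps, np.zeros_like(eps))))
        assert fit.K_A == 0.0

    def test_excludes_large_strains(self):
        eps = np.concatenate([np.linspace(0.001, 0.049, 30), [0.2, 0.3]])
        gam = 303.0 * eps
        gam[-2:] = 1e6  # poisoned points above the fit window
        fit = fit_area_compressibility(list(zip(eps, gam)))
        assert fit.K_A == pytest.approx(303.0)
        assert fit.n == 30

    def test_too_few_pairs_rejected(self):
        with pytest.raises(MembraneError):
            fit_area_compressibility([(0.01, 3.0)] * 4)

    def test_monte_carlo_recovery(self):
        # 100 replicates of 50 noisy pairs: mean recovered K_A within
        # 3 standard errors of the planted truth
        rng = np.random.default_rng(42)
        truth = 303.0
        fits = []
        for _ in range(100):
            eps = rng.uniform(0.0, 0.05, 50)
            gam = truth * eps + rng.normal(0, 5.0, 50)
            fits.append(fit_area_compressibility(list(zip(eps, gam))).K_A)
        fits = np.array(fits)
        se = fits.std(ddof=1) / 10
        assert abs(fits.mean() - truth) < 3 * se + 1e-9

    @given(c=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        eps = np.linspace(0.001, 0.049, 25)
        gam = 150.0 * eps + 0.5 * np.sin(np.arange(25))
        k1 = fit_area_compressibility(list(zip(eps, gam))).K_A
        k2 = fit_area_compressibility(list(zip(eps, c * gam))).K_A
        assert k2 == pytest.approx(c * k1, rel=1e-9)


class TestDetectTensionJump:
    def test_constant_series_negative(self):
        s = TensionSeries(steps=np.arange(300), gamma=np.full(300, 5.0))
        assert not detect_tension_jump(s, min_drop=0.1).positive

    def test_planted_drop_located(self):
        s = synth_tension_series(303.0, np.full(1000, 0.02), noise_sd=0.5,
                                 pore_step=500, post_pore_drop=5.0, seed=1)
        call = detect_tension_jump(s)
        assert call.positive
        assert abs(call.location - 500) <= 1
        assert call.magnitude == pytest.approx(5.0, rel=0.2)

    def test_false_positive_rate_below_one_percent(self):
        fp = 0
        for seed in range(100):
            s = synth_tension_series(303.0, np.full(600, 0.02), noise_sd=1.0,
                                     seed=seed)
            if detect_tension_jump(s).positive:
                fp += 1
        assert fp < 1  # < 1 %

    def test_window_too_long_rejected(self):
        s = TensionSeries(steps=np.arange(80), gamma=np.zeros(80))
        with pytest.raises(MembraneError):
            detect_tension_jump(s, window=50)


class TestDetectPoreGeometric:
    def test_pristine_membrane_negative(self, small_membrane):
        assert not detect_pore_geometric(small_membrane).positive

    def test_planted_pore_detected_with_radius(self, small_membrane):
        cfg = plant_pore(small_membrane, 2.0, seed=1)
        call = detect_pore_geometric(cfg, grid=0.5)
        assert call.positive
        assert call.magnitude == pytest.approx(2.0, abs=0.5)

    def test_grid_too_coarse_rejected(self, small_membrane):
        with pytest.raises(MembraneError):
            detect_pore_geometric(small_membrane, grid=20.0)

    def test_matches_flood_fill_oracle_on_toy_grids(self):
        # independent 6-neighbour-expanded BFS flood fill on random toy
        # occupancy grids must agree on the crossing verdict
        def oracle_crosses(occ, k_lo, k_hi):
            nx, ny, nz = occ.shape
            seen = np.zeros_like(occ, dtype=bool)
            import collections
            verdict = False
            for sx in range(nx):
                for sy in range(ny):
                    for sz in range(nz):
                        if not occ[sx, sy, sz] or seen[sx, sy, sz]:
                            continue
                        comp = []
                        dq = collections.deque([(sx, sy, sz)])
                        seen[sx, sy, sz] = True
                        while dq:
                            x, y, z = dq.popleft()
                            comp.append((x, y, z))
                            for dx in (-1, 0, 1):
                                for dy in (-1, 0, 1):
                                    for dz in (-1, 0, 1):
                                        nx2, ny2, nz2 = x + dx, y + dy, z + dz
                                        if (0 <= nx2 < nx and 0 <= ny2 < ny
                                                and 0 <= nz2 < nz
                                                and occ[nx2, ny2, nz2]
                                                and not seen[nx2, ny2, nz2]):
                                            seen[nx2, ny2, nz2] = True
                                            dq.append((nx2, ny2, nz2))
                        ks = [c[2] for c in comp]
                        if min(ks) <= k_lo and max(ks) >= k_hi:
                            verdict = True
            return verdict

        rng = np.random.default_rng(7)
        grid = 1.0
        for trial in range(10):
            occ = rng.random((10, 10, 10)) < 0.25
            # build a config whose waters occupy exactly these voxels and
            # whose tails put the core band at k in [4, 6]
            waters = np.argwhere(occ) + 0.5
            tails = np.array([[5.0, 5.0, 4.5], [5.0, 5.0, 6.5]])
            heads = np.array([[5.0, 5.0, 2.0], [5.0, 5.0, 9.0]])
            coords = np.concatenate([waters, tails, heads])
            kinds = (["water"] * len(waters) + ["tail", "tail"]
                     + ["head", "head"])
            leaf = (["none"] * len(waters) + ["inner", "outer",
                                              "inner", "outer"])
            cfg = make_config(coords, kinds, leaf)
            call = detect_pore_geometric(cfg, grid=grid)
            z0 = 5.0
            half = float(np.mean(np.abs(np.array([4.5, 6.5]) - z0)))
            k_lo = int((z0 - half) / grid)
            k_hi = min(int((z0 + half) / grid), 9)
            assert call.positive == oracle_crosses(occ, k_lo, k_hi)


class TestInterdigitationIndex:
    def test_fully_separated_tails(self):
        coords = [[1, 1, 8.0], [2, 2, 8.2], [1, 1, 2.0], [2, 2, 2.2],
                  [1, 1, 9.0], [1, 1, 1.0]]
        kinds = ["tail", "tail", "tail", "tail", "head", "head"]
        leaf = ["outer", "outer", "inner", "inner", "outer", "inner"]
        cfg = make_config(coords, kinds, leaf)
        assert interdigitation_index(cfg) == pytest.approx(0.0)

    def test_identical_distributions(self):
        z = [5.0, 5.1, 5.2, 5.3]
        coords = [[1, 1, v] for v in z] + [[2, 2, v] for v in z] \
            + [[1, 1, 9.0], [1, 1, 1.0]]
        kinds = ["tail"] * 8 + ["head", "head"]
        leaf = ["outer"] * 4 + ["inner"] * 4 + ["outer", "inner"]
        cfg = make_config(coords, kinds, leaf)
        assert interdigitation_index(cfg) == pytest.approx(1.0)

    def test_monotone_in_planted_depth(self, small_membrane):
        depths = np.linspace(0.0, 1.9, 8)
        idx = [interdigitation_index(plant_interdigitation(small_membrane, d))
               for d in depths]
        assert all(b >= a - 1e-12 for a, b in zip(idx, idx[1:]))
        assert idx[-1] > idx[0]


class TestPartitionCoefficient:
    def test_no_core_water(self, small_membrane):
        res = partition_coefficient(small_membrane)
        assert res.K == 0.0
        assert res.log10_K == float("-inf")

    def test_planted_log_k_recovery(self, small_membrane):
        cfg = set_core_water(small_membrane, -1.73, seed=3)
        res = partition_coefficient(cfg)
        # one-bead quantization on the planted count
        assert res.core_water_molecules == pytest.approx(
            cfg.metadata["core_water_beads"] * 4, abs=4)
        assert res.log10_K == pytest.approx(-1.73, abs=0.02)

    def test_planted_bulk_equivalence(self):
        # K = 1 needs bulk-level core density; use a small box so the
        # bead budget suffices
        m = build_membrane(box=(10.0, 10.0, 12.0), n_lipids=100,
                           hydration_beads=8000, seed=2)
        cfg = set_core_water(m, 0.0, seed=4)
        res = partition_coefficient(cfg)
        assert res.log10_K == pytest.approx(0.0, abs=0.01)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(11)
        box = np.array([6.0, 6.0, 6.0])
        n_t, n_w = 40, 200
        coords = np.concatenate([
            rng.uniform(0, 6, (n_t, 3)) * [1, 1, 0.2] + [0, 0, 2.4],
            rng.uniform(0, 6, (n_w, 3)),
            [[3.0, 3.0, 4.5], [3.0, 3.0, 1.5]],
        ])
        kinds = ["tail"] * n_t + ["water"] * n_w + ["head", "head"]
        leaf = ["outer"] * n_t + ["none"] * n_w + ["outer", "inner"]
        cfg = make_config(coords, kinds, leaf, box=box)
        res = partition_coefficient(cfg, cutoff=0.52)
        # O(N^2) minimum-image oracle
        t = cfg.coords[cfg.select(kind="tail")]
        w = cfg.coords[cfg.select(kind="water")]
        d = np.abs(w[:, None, :] - t[None, :, :])
        d = np.minimum(d, box - d)
        dist = np.sqrt((d ** 2).sum(axis=2))
        n_core = int(np.sum(dist.min(axis=1) <= 0.52))
        assert res.core_water_molecules == 4 * n_core

    def test_invariant_under_periodic_xy_translation(self, small_membrane):
        cfg = set_core_water(small_membrane, -1.5, seed=5)
        res0 = partition_coefficient(cfg)
        shifted = cfg.copy()
        shifted.coords[:, 0] = (shifted.coords[:, 0] + 7.3) % shifted.box[0]
        shifted.coords[:, 1] = (shifted.coords[:, 1] + 2.9) % shifted.box[1]
        res1 = partition_coefficient(shifted)
        assert res1.core_water_molecules == res0.core_water_molecules

    def test_no_tails_rejected(self):
        cfg = make_config([[1, 1, 1], [2, 2, 9]], ["head", "head"],
                          ["inner", "outer"])
        with pytest.raises(MembraneError):
            partition_coefficient(cfg)


class TestPermeabilityChange:
    def _res(self, K):
        from axoporate.membrane_metrics import PartitionResult
        return PartitionResult(core_water_molecules=1, membrane_volume_L=1e-21,
                               conc_mem=K * 55.5, K=K,
                               log10_K=np.log10(K) if K > 0 else float("-inf"))

    def test_no_change(self):
        assert permeability_change(self._res(0.02), self._res(0.02)) == 0.0

    def test_forty_percent(self):
        assert permeability_change(self._res(0.028), self._res(0.02)) \
            == pytest.approx(40.0)

    def test_fifty_one_percent(self):
        assert permeability_change(self._res(0.0302), self._res(0.02)) \
            == pytest.approx(51.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(MembraneError):
            permeability_change(self._res(0.02), self._res(0.0))


class TestDetectorAgreement:
    def test_joint_fixtures_agree(self, small_membrane):
        # pore <-> tension drop planted together; the two detectors must
        # agree in >= 99/100 seeded trials
        agree = 0
        for seed in range(50):
            plant = seed % 2 == 0
            cfg = plant_pore(small_membrane, 2.0 if plant else 0.0, seed=seed)
            s = synth_tension_series(
                303.0, np.full(400, 0.02), noise_sd=0.5,
                pore_step=200 if plant else None,
                post_pore_drop=5.0, seed=seed)
            g = detect_pore_geometric(cfg).positive
            t = detect_tension_jump(s).positive
            if g == t == plant:
                agree += 1
        assert agree >= 50 * 0.99
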