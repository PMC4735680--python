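import math

import numpy as np
import pytest

from cgmem.constants import KB_J
from cgmem.errors import DegenerateBilayerError, FitError, ResolutionError
from cgmem.membrane import (
    FluctuationSpectrum,
    MembraneTopology,
    UndulationSurface,
    assign_leaflets,
    block_average,
    count_inserted_cations,
    detect_saturation,
    fit_bending_modulus,
    reconstruct_surface,
    undulation_spectrum,
)

from conftest import make_config


def _bilayer_config(params, n_side=8, spacing=0.8, z_upper=None, z_lower=None, box_z=12.0):
    """Phosphate-only bilayer on an n_side x n_side lattice per leaflet."""
    L = n_side * spacing
    pos, types, mols = [], [], []
    truth = []
    mid = box_z / 2
    mol = 0
    for leaflet, zfun, sign in (("upper", z_upper, 1), ("lower", z_lower, -1)):
        for i in range(n_side):
            for j in range(n_side):
                x = (i + 0.5) * spacing
                y = (j + 0.5) * spacing
                z = mid + sign * 2.0 if zfun is None else mid + zfun(x, y)
                pos.append([x, y, z])
                types.append("PH")
                mols.append(mol)
                truth.append(leaflet)
                mol += 1
    cfg = make_config(pos, types, box=(L, L, box_z), molecule_ids=np.array(mols))
    topo = MembraneTopology.from_config(cfg, params)
    return cfg, topo, truth


class TestAssignLeaflets:
    def test_flat_even_split(self, params):
        cfg, topo, truth = _bilayer_config(params)
        a = assign_leaflets(cfg, topo)
        assert int(np.sum(a.labels == "upper")) == 64
        assert int(np.sum(a.labels == "lower")) == 64
        assert list(a.labels) == truth

    def test_translation_invariance(self, params):
        cfg, topo, _ = _bilayer_config(params)
        a = assign_leaflets(cfg, topo)
        cfg2 = cfg.copy()
        cfg2.positions[:, 2] = np.mod(cfg2.positions[:, 2] + 1.0, cfg2.box[2])
        b = assign_leaflets(cfg2, topo)
        assert np.array_equal(a.labels, b.labels)

    def test_strongly_bent_bilayer(self, params):
        # sinusoidal bend, amplitude 1.5 nm: grid-local midplane must track it
        cfg, topo, truth = _bilayer_config(
            params,
            n_side=16,
            spacing=0.8,
            z_upper=lambda x, y: 2.0 + 1.5 * math.sin(2 * math.pi * x / 12.8),
            z_lower=lambda x, y: -2.0 + 1.5 * math.sin(2 * math.pi * x / 12.8),
            box_z=16.0,
        )
        a = assign_leaflets(cfg, topo, grid=8)
        assert list(a.labels) == truth

    def test_degenerate_bilayer_rejected(self, params):
        cfg, topo, _ = _bilayer_config(params, z_upper=lambda x, y: 2.0, z_lower=lambda x, y: 1.0)
        with pytest.raises(DegenerateBilayerError):
            # all phosphates well above the box-relative mean minus spread: craft
            # truly one-sided system instead
            one_sided = cfg.copy()
            one_sided.positions[:, 2] = cfg.box[2] / 2 + 2.0
            assign_leaflets(one_sided, topo)


class TestInsertionCounting:
    def test_constructed_ratio(self, params):
        from cgmem.synth import ToyBilayerSpec, build_toy_bilayer

        spec = ToyBilayerSpec(
            lipids_per_leaflet=64, cation_count=38, inserted_per_lipid_upper=38 / 64, seed=8
        )
        cfg, truth = build_toy_bilayer(spec, params)
        topo = MembraneTopology.from_config(cfg, params)
        a = assign_leaflets(cfg, topo)
        row = count_inserted_cations(cfg, topo, a)
        assert row["inserted_upper"] == 38
        assert row["ratio_upper"] == 38 / 64 == 0.59375

    def test_bulk_cations_not_counted(self, params):
        from cgmem.synth import ToyBilayerSpec, build_toy_bilayer

        spec = ToyBilayerSpec(lipids_per_leaflet=16, cation_count=5, seed=9)
        cfg, _ = build_toy_bilayer(spec, params)
        topo = MembraneTopology.from_config(cfg, params)
        a = assign_leaflets(cfg, topo)
        row = count_inserted_cations(cfg, topo, a)
        assert row["inserted_upper"] == 0
        assert row["inserted_lower"] == 0

    def test_midplane_tie_counts_upper(self, params):
        cfg, topo, _ = _bilayer_config(params)
        a = assign_leaflets(cfg, topo)
        # append one cation ring bead exactly on the midplane reference height
        pos = np.vstack([cfg.positions, [[3.2, 3.2, a.z_ref]]])
        types = np.append(cfg.bead_types, "RI")
        mols = np.append(cfg.molecule_ids, cfg.molecule_ids.max() + 1)
        cfg2 = make_config(pos, types, box=tuple(cfg.box), molecule_ids=mols)
        topo2 = MembraneTopology.from_config(cfg2, params)
        row = count_inserted_cations(cfg2, topo2, a)
        assert row["inserted_upper"] == 1
        assert row["inserted_lower"] == 0

    def test_reorder_and_translate_conserved(self, params):
        from cgmem.synth import ToyBilayerSpec, build_toy_bilayer

        spec = ToyBilayerSpec(
            lipids_per_leaflet=16, cation_count=12, inserted_per_lipid_upper=0.5, seed=10
        )
        cfg, _ = build_toy_bilayer(spec, params)
        topo = MembraneTopology.from_config(cfg, params)
        r0 = count_inserted_cations(cfg, topo, assign_leaflets(cfg, topo))
        # rigid translation (wrapped)
        cfg_t = cfg.copy()
        cfg_t.positions = np.mod(cfg_t.positions + np.array([0.7, -1.1, 2.3]), cfg_t.box)
        r1 = count_inserted_cations(cfg_t, topo, assign_leaflets(cfg_t, topo))
        # bead re-ordering
        perm = np.random.default_rng(0).permutation(cfg.n_beads)
        cfg_p = make_config(
            cfg.positions[perm], cfg.bead_types[perm], box=tuple(cfg.box),
            molecule_ids=cfg.molecule_ids[perm],
        )
        topo_p = MembraneTopology.from_config(cfg_p, params)
        r2 = count_inserted_cations(cfg_p, topo_p, assign_leaflets(cfg_p, topo_p))
        for r in (r1, r2):
            assert r["ratio_upper"] == r0["ratio_upper"]
            assert r["ratio_lower"] == r0["ratio_lower"]


class TestSaturation:
    def test_constant_series(self):
        r = detect_saturation(np.full(40, 0.6), window=10)
        assert r.defined
        assert r.ratio == pytest.approx(0.6)
        assert r.onset_index == 0

    def test_logistic_plateau_recovered(self):
        t = np.arange(400, dtype=float)
        p = 0.61
        series = p / (1 + np.exp(-(t - 80) / 15))
        rng = np.random.default_rng(5)
        series = series + rng.normal(scale=0.004, size=len(series))
        r = detect_saturation(series, window=100)
        assert r.defined
        assert r.ratio == pytest.approx(p, rel=0.02)
        assert 0 < r.onset_index < 200

    def test_linear_rise_undefined(self):
        r = detect_saturation(np.linspace(0, 1, 100), window=30)
        assert not r.defined

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_saturation(np.zeros(10), window=10)


class TestReconstructSurface:
    def test_flat_leaflet_zero(self, params):
        cfg, topo, _ = _bilayer_config(params, n_side=8)
        a = assign_leaflets(cfg, topo)
        s = reconstruct_surface(cfg, topo, a, n_grid=8)
        assert np.allclose(s.heights, 0.0, atol=1e-12)

    def test_cosine_surface_recovered(self, params):
        n = 16
        L = n * 0.8
        cfg, topo, _ = _bilayer_config(
            params,
            n_side=n,
            spacing=0.8,
            z_upper=lambda x, y: 2.0 + 0.5 * math.cos(2 * math.pi * x / L),
            z_lower=lambda x, y: -2.0,
            box_z=16.0,
        )
        a = assign_leaflets(cfg, topo, grid=4)
        s = reconstruct_surface(cfg, topo, a, n_grid=16)
        x = (np.arange(n) + 0.5) * 0.8
        expect = 0.5 * np.cos(2 * np.pi * x / L)
        expect = expect - expect.mean()
        got = s.heights  # (ix, iy) grid
        for iy in range(n):
            assert np.allclose(got[:, iy], expect, atol=1e-6)

    def test_hole_filled_to_neighbor_mean(self, params):
        cfg, topo, _ = _bilayer_config(params, n_side=8)
        # delete one upper-leaflet lipid -> one empty cell, neighbors all 0
        keep = np.ones(cfg.n_beads, bool)
        keep[10] = False
        cfg2 = make_config(
            cfg.positions[keep], cfg.bead_types[keep], box=tuple(cfg.box),
            molecule_ids=cfg.molecule_ids[keep],
        )
        topo2 = MembraneTopology.from_config(cfg2, params)
        a = assign_leaflets(cfg2, topo2)
        s = reconstruct_surface(cfg2, topo2, a, n_grid=8)
        assert np.allclose(s.heights, 0.0, atol=1e-12)

    def test_too_sparse_rejected(self, params):
        cfg, topo, _ = _bilayer_config(params, n_side=4)
        a = assign_leaflets(cfg, topo)
        with pytest.raises(ResolutionError):
            reconstruct_surface(cfg, topo, a, n_grid=16)

    def test_power_of_two_required(self, params):
        cfg, topo, _ = _bilayer_config(params)
        a = assign_leaflets(cfg, topo)
        with pytest.raises(ValueError):
            reconstruct_surface(cfg, topo, a, n_grid=12)


class TestSpectrum:
    def test_zero_surfaces(self):
        surfs = [UndulationSurface(np.zeros((16, 16)), 20.0) for _ in range(3)]
        sp = undulation_spectrum(surfs)
        assert np.all(sp.intensity == 0.0)
        assert np.all(sp.q_values > 0)  # q = 0 excluded

    def test_cosine_mode_intensity(self):
        n, L, a, m = 32, 25.0, 0.3, 3
        x = np.arange(n) * L / n
        h = a * np.cos(2 * np.pi * m * x / L)[:, None] * np.ones(n)[None, :]
        sp = undulation_spectrum([UndulationSurface(h, L)])
        area = L * L
        q1 = 2 * np.pi * m / L
        # 2-D spectrum: all intensity in the (+-m, 0) modes, each A a^2/4
        assert sp.intensity_2d[m, 0] == pytest.approx(area * a * a / 4, rel=1e-10)
        assert sp.intensity_2d[n - m, 0] == pytest.approx(area * a * a / 4, rel=1e-10)
        masked = sp.intensity_2d.copy()
        masked[m, 0] = masked[n - m, 0] = 0.0
        assert np.max(np.abs(masked)) < 1e-12
        # radially: only the |q1| bin carries intensity
        nz = sp.intensity > 1e-12
        assert nz.sum() == 1
        assert sp.q_values[nz][0] == pytest.approx(q1)

    def test_parseval(self):
        rng = np.random.default_rng(6)
        h = rng.normal(size=(32, 32))
        h -= h.mean()
        sp = undulation_spectrum([UndulationSurface(h, 10.0)])
        h_hat = np.fft.fft2(h) / 32**2
        assert np.sum(np.abs(h_hat) ** 2) == pytest.approx(np.mean(h**2), rel=1e-10)

    def test_uniform_offset_invariance(self):
        rng = np.random.default_rng(7)
        h = rng.normal(size=(16, 16))
        a = undulation_spectrum([UndulationSurface(h - h.mean(), 10.0)])
        b = undulation_spectrum([UndulationSurface(h - h.mean() + 5.0, 10.0, )])
        assert np.allclose(a.intensity, b.intensity, atol=1e-12)

    def test_mixed_grids_rejected(self):
        with pytest.raises(ValueError):
            undulation_spectrum(
                [UndulationSurface(np.zeros((16, 16)), 10.0), UndulationSurface(np.zeros((32, 32)), 10.0)]
            )


class TestBendingFit:
    def _exact_spectrum(self, kappa, t=303.0, L=25.0, n=32):
        dq = 2 * np.pi / L
        q = dq * np.sqrt(np.arange(1, 20, dtype=float))
        s = KB_J * t / (kappa * q**4)
        return FluctuationSpectrum(
            q_values=q, intensity=s, stderr=np.full_like(q, np.nan), n_frames=1,
            box_edge=L, grid=n,
        )

    def test_exact_inversion(self):
        kappa = 10e-20
        fit = fit_bending_modulus(self._exact_spectrum(kappa), 303.0, q_max=1.0)
        assert fit.kappa == pytest.approx(kappa, rel=1e-10)
        assert fit.kappa_e20 == pytest.approx(10.0, rel=1e-10)
        assert fit.goodness == pytest.approx(1.0, abs=1e-10)

    def test_temperature_scaling(self):
        sp = self._exact_spectrum(10e-20)
        k1 = fit_bending_modulus(sp, 303.0, q_max=1.0).kappa
        k2 = fit_bending_modulus(sp, 606.0, q_max=1.0).kappa
        assert k2 == pytest.approx(2 * k1, rel=1e-12)

    def test_too_few_bins(self):
        sp = self._exact_spectrum(10e-20)
        with pytest.raises(FitError):
            fit_bending_modulus(sp, 303.0, q_max=sp.q_values[1])

    def test_helfrich_round_trip_500_frames(self, helfrich_500):
        spec, surfs = helfrich_500
        fit = fit_bending_modulus(undulation_spectrum(surfs), spec.temperature, q_max=1.0)
        assert fit.kappa == pytest.approx(spec.kappa, rel=0.05)

    def test_bias_decreases_with_frames(self, helfrich_500):
        spec, surfs = helfrich_500
        f50 = fit_bending_modulus(undulation_spectrum(surfs[:50]), spec.temperature, q_max=1.0)
        f500 = fit_bending_modulus(undulation_spectrum(surfs), spec.temperature, q_max=1.0)
        assert abs(f50.kappa - spec.kappa) / spec.kappa < 0.15
        assert abs(f500.kappa - spec.kappa) <= abs(f50.kappa - spec.kappa)

    def test_full_path_with_lipid_sampling(self, params):
        # Helfrich surfaces -> phosphate lattice configs -> reconstruct ->
        # spectrum -> fit; discretization-tolerant 10% bound
        from cgmem.synth import HelfrichSpec, sample_helfrich_surfaces

        n = 16
        spec = HelfrichSpec(
            kappa=22.6e-20, temperature=303.0, box_edge=12.8, grid=n, n_frames=500, seed=21
        )
        surfs = sample_helfrich_surfaces(spec)
        spacing = spec.box_edge / n
        rec = []
        for s in surfs:
            def zup(x, y, _s=s):
                i = int(x / spacing) % n
                j = int(y / spacing) % n
                return 2.0 + _s.heights[i, j]

            cfg, topo, _ = _bilayer_config(
                params, n_side=n, spacing=spacing, z_upper=zup, z_lower=lambda x, y: -2.0,
                box_z=16.0,
            )
            a = assign_leaflets(cfg, topo, grid=4)
            rec.append(reconstruct_surface(cfg, topo, a, n_grid=n))
        fit = fit_bending_modulus(undulation_spectrum(rec), spec.temperature, q_max=1.0)
        assert fit.kappa == pytest.approx(spec.kappa, rel=0.10)


class TestBlockAverage:
    def test_constant_zero_error(self):
        m, e = block_average(np.full(100, 2.5), 5)
        assert m == 2.5
        assert e == 0.0

    def test_gaussian_standard_error(self):
        rng = np.random.default_rng(12)
        x = rng.normal(loc=1.0, scale=2.0, size=10000)
        m, e = block_average(x, 10)
        assert m == pytest.approx(1.0, abs=0.1)
        assert e == pytest.approx(2.0 / math.sqrt(10000), rel=0.3)

    def test_permutation_within_block_invariance(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=90)
        m0, _ = block_average(x, 3)
        y = x.copy()
        for b in range(3):
            seg = slice(b * 30, (b + 1) * 30)
            y[seg] = rng.permutation(y[seg])
        m1, _ = block_average(y, 3)
        assert m1 == pytest.approx(m0, rel=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            block_average(np.zeros(10), 1)
        with pytest.raises(ValueError):
            block_average(np.zeros(3), 5)
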