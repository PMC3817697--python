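"""Supercell structure factors, Patterson searches, phase extension."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hybridfit import em_mr, synth
from hybridfit.em_mr import (
    PhaseSet,
    StructureFactorSet,
    embed_in_supercell,
    map_to_sf,
    mean_phase_error,
    patterson_score_function,
    phase_extend,
    read_hkl,
    resolution_filter,
    rotation_search,
    sf_to_map,
    translation_search,
    write_hkl,
)
from hybridfit.grids_io import DensityMap


def dft_triple_sum(values):
    """Independent brute-force DFT with the +2πi kernel (oracle)."""
    nx, ny, nz = values.shape
    out = np.zeros((nx, ny, nz), dtype=complex)
    for h in range(nx):
        for k in range(ny):
            for l in range(nz):
                acc = 0.0j
                for x in range(nx):
                    for y in range(ny):
                        for z in range(nz):
                            acc += values[x, y, z] * np.exp(
                                2j
                                * np.pi
                                * (h * x / nx + k * y / ny + l * z / nz)
                            )
                out[h, k, l] = acc
    return out


@pytest.fixture(scope="module")
def random_map8():
    rng = np.random.default_rng(0)
    return DensityMap(rng.normal(size=(8, 8, 8)), [2.0] * 3, [0.0] * 3)


class TestMapToSF:
    def test_matches_triple_sum_oracle(self, random_map8):
        sf = map_to_sf(random_map8)
        oracle = dft_triple_sum(random_map8.values)
        lookup = {tuple(h): f for h, f in zip(map(tuple, sf.hkl), sf.f_complex)}
        scale = np.abs(oracle).max()
        for h in range(8):
            for k in range(8):
                for l in range(8):
                    hs = (h - 8 if h >= 4 else h, k - 8 if k >= 4 else k, l - 8 if l >= 4 else l)
                    assert abs(lookup[hs] - oracle[h, k, l]) < 1e-10 * scale

    def test_friedel_symmetry_exact(self, random_map8):
        sf = map_to_sf(random_map8)
        lookup = {tuple(h): f for h, f in zip(map(tuple, sf.hkl), sf.f_complex)}
        checked = 0
        for (h, k, l), f in lookup.items():
            mate = (-h, -k, -l)
            if mate in lookup:
                assert abs(lookup[mate] - np.conj(f)) < 1e-12 * (1 + abs(f))
                checked += 1
        assert checked >= 7**3  # bins off the Nyquist planes all have mates

    def test_parseval(self, random_map8):
        sf = map_to_sf(random_map8)
        n = random_map8.values.size
        lhs = (sf.amplitude**2).sum()
        rhs = n * (random_map8.values**2).sum()
        assert abs(lhs - rhs) < 1e-8 * rhs

    def test_f000_is_density_sum(self, random_map8):
        sf = map_to_sf(random_map8)
        i = np.flatnonzero((sf.hkl == 0).all(axis=1))[0]
        f000 = sf.f_complex[i]
        assert f000 == pytest.approx(random_map8.values.sum(), abs=1e-9)

    def test_constant_map_only_f000(self):
        m = DensityMap(np.full((8, 8, 8), 3.0), [2.0] * 3, [0.0] * 3)
        sf = map_to_sf(m)
        nonzero = sf.amplitude > 1e-9
        assert nonzero.sum() == 1
        assert (sf.hkl[nonzero] == 0).all()

    def test_centred_gaussian_phases_zero(self):
        # Gaussian centred at the cell origin (grid point 0): real, even map
        n, vs = 16, 2.0
        ax = np.arange(n) * vs
        ax = np.minimum(ax, n * vs - ax)  # periodic distance to origin
        r2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
        m = DensityMap(np.exp(-r2 / (2.0 * 3.0**2)), [vs] * 3, [0.0] * 3)
        sf = map_to_sf(m)
        big = sf.amplitude > 1e-6 * sf.amplitude.max()
        assert np.abs(sf.phase[big]).max() < 1e-6


class TestSfToMap:
    def test_round_trip(self):
        rng = np.random.default_rng(5)
        m = DensityMap(rng.normal(size=(12, 10, 8)), [2.0] * 3, [0.0] * 3)
        back = sf_to_map(map_to_sf(m), m.shape)
        assert np.abs(back.values - m.values).max() < 1e-6 * np.abs(m.values).max()

    def test_f000_only_gives_constant(self, random_map8):
        sf = map_to_sf(random_map8)
        keep = (sf.hkl == 0).all(axis=1)
        only000 = StructureFactorSet(
            sf.cell, "P1", sf.hkl[keep], sf.amplitude[keep], sf.phase[keep]
        )
        m = sf_to_map(only000, (8, 8, 8))
        assert np.ptp(m.values) < 1e-12

    def test_truncation_matches_direct_fourier_cut(self, holo_map):
        from hybridfit.map_algebra import pad_to_cube
        import scipy.fft

        cube = pad_to_cube(holo_map)
        sf = map_to_sf(cube)
        d_cut = 10.0
        kept = resolution_filter(sf, d_cut, 1e6)
        # keep F000 too: resolution_filter drops it (d = inf > d_max is fine);
        # add it back for a faithful truncated synthesis
        f000 = (sf.hkl == 0).all(axis=1)
        kept = StructureFactorSet(
            sf.cell,
            "P1",
            np.vstack([kept.hkl, sf.hkl[f000]]),
            np.concatenate([kept.amplitude, sf.amplitude[f000]]),
            np.concatenate([kept.phase, sf.phase[f000]]),
        )
        trunc = sf_to_map(kept, cube.shape)
        # oracle: direct Fourier truncation of the map
        ft = scipy.fft.fftn(cube.values)
        freqs = scipy.fft.fftfreq(cube.shape[0], d=cube.voxel_size[0])
        s2 = (
            freqs[:, None, None] ** 2
            + freqs[None, :, None] ** 2
            + freqs[None, None, :] ** 2
        )
        ft[s2 > 1.0 / d_cut**2] = 0.0
        oracle = scipy.fft.ifftn(ft).real
        assert np.abs(trunc.values - oracle).max() < 1e-9 * np.abs(oracle).max()

    def test_unphased_set_rejected(self, random_map8):
        sf = map_to_sf(random_map8).amplitudes_only()
        with pytest.raises(ValueError):
            sf_to_map(sf, (8, 8, 8))


class TestSupercell:
    def test_factor_one_identity(self, holo_map):
        out = embed_in_supercell(holo_map, 1.0)
        assert out.shape == holo_map.shape
        assert np.array_equal(out.values, holo_map.values)

    def test_factor_five_conserves_sum(self, random_map8):
        out = embed_in_supercell(random_map8, 5.0)
        assert out.shape == (40, 40, 40)
        assert out.values.sum() == pytest.approx(random_map8.values.sum(), abs=1e-9)

    def test_content_centred_and_max_preserved(self):
        m = DensityMap(np.zeros((8, 8, 8)), [1.0] * 3, [0.0] * 3)
        m.values[1, 1, 1] = 7.0  # off-centre content
        out = embed_in_supercell(m, 2.0)
        assert out.values.max() == 7.0
        peak = np.unravel_index(np.argmax(out.values), out.shape)
        assert peak == (5, 5, 5)  # start offset (4,4,4) + original (1,1,1)
        # physical position is unchanged: origin shifted by the padding
        pos_before = m.origin + np.array([1, 1, 1]) * m.voxel_size
        pos_after = out.origin + np.array(peak) * out.voxel_size
        assert np.allclose(pos_before, pos_after)


class TestResolutionFilter:
    def test_matches_bruteforce_per_reflection_test(self, random_map8):
        sf = map_to_sf(embed_in_supercell(random_map8, 3.0))
        band = resolution_filter(sf, 4.0, 30.0)
        d = sf.d
        expected = {
            tuple(h) for h, di in zip(map(tuple, sf.hkl), d) if 4.0 <= di <= 30.0
        }
        assert {tuple(h) for h in band.hkl} == expected

    def test_idempotent_and_nested(self, random_map8):
        sf = map_to_sf(random_map8)
        a = resolution_filter(sf, 5.0, 30.0)
        b = resolution_filter(a, 5.0, 30.0)
        assert len(a) == len(b)
        nested = resolution_filter(resolution_filter(sf, 4.0, 40.0), 5.0, 30.0)
        direct = resolution_filter(sf, 5.0, 30.0)
        assert sorted(map(tuple, nested.hkl)) == sorted(map(tuple, direct.hkl))

    def test_empty_band_flagged_not_fatal(self, random_map8):
        sf = map_to_sf(random_map8)
        out = resolution_filter(sf, 1000.0, 2000.0)
        assert len(out) == 0

    def test_invalid_band_rejected(self, random_map8):
        sf = map_to_sf(random_map8)
        with pytest.raises(ValueError):
            resolution_filter(sf, 30.0, 4.0)


@pytest.fixture(scope="module")
def mr_fixture():
    """Subunit map embedded in a 5x P1 supercell, plus rotated observations."""
    model = synth.toy_complex()
    sub = synth.make_subcomplex(model, {"A", "C"})
    spec = synth.SimulationSpec()
    dmap = synth.simulate_map(sub, spec)
    big = embed_in_supercell(dmap, 5.0)
    model_sf = resolution_filter(map_to_sf(big), 6.0, 30.0)
    return {"sub": sub, "map": dmap, "model_sf": model_sf, "spec": spec}


class TestRotationSearch:
    def test_planted_identity_top_ranked(self, mr_fixture):
        obs = mr_fixture["model_sf"].amplitudes_only()
        ranked = rotation_search(
            mr_fixture["model_sf"], obs, radius_of_integration=25.0,
            angular_step_deg=20.0,
        )
        top, score = ranked[0]
        assert np.degrees(top.magnitude()) <= 20.0
        assert score > 0.9

    def test_planted_rotation_recovered(self, mr_fixture):
        rot_true = Rotation.from_rotvec(np.radians(25.0) * np.array([0, 1.0, 0]))
        sub, dmap, spec = mr_fixture["sub"], mr_fixture["map"], mr_fixture["spec"]
        moved = sub.transformed(
            rot_true.as_matrix(), (np.eye(3) - rot_true.as_matrix()) @ sub.centroid
        )
        rotated_map = synth.simulate_map(
            moved, spec, origin=dmap.origin, shape=dmap.shape
        )
        obs = resolution_filter(
            map_to_sf(embed_in_supercell(rotated_map, 5.0)), 6.0, 30.0
        ).amplitudes_only()
        ranked = rotation_search(
            mr_fixture["model_sf"], obs, radius_of_integration=25.0,
            angular_step_deg=15.0,
        )
        top, _ = ranked[0]
        # the Patterson cannot tell R from its centrosymmetric image
        err = np.degrees((top.inv() * rot_true).magnitude())
        err_inv = np.degrees((top.inv() * rot_true).inv().magnitude())
        assert min(err, err_inv) <= 15.0

    def test_patterson_centrosymmetry_of_score(self, mr_fixture):
        obs = mr_fixture["model_sf"].amplitudes_only()
        score = patterson_score_function(mr_fixture["model_sf"], obs, 25.0)
        rng = np.random.default_rng(2)
        for _ in range(3):
            R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
            assert score(R) == pytest.approx(score(-R), abs=1e-9)

    def test_radius_larger_than_supercell_rejected(self, mr_fixture):
        obs = mr_fixture["model_sf"].amplitudes_only()
        with pytest.raises(ValueError, match="radius of integration"):
            rotation_search(mr_fixture["model_sf"], obs, radius_of_integration=1e4)


class TestTranslationSearch:
    CELL = np.array([60.0, 50.0, 55.0])

    @pytest.fixture(scope="class")
    @staticmethod
    def placed_model():
        model = synth.toy_complex()
        sub = synth.make_subcomplex(model, {"A", "C"})
        return sub.transformed(
            np.eye(3), np.array([15.0, 12.0, 15.0]) - sub.positions.min(axis=0)
        )

    def test_p1_degenerate(self, placed_model):
        xtal = synth.make_crystal(placed_model, "P1", self.CELL, d=5.0)
        mdl = synth.structure_factors_direct(placed_model, self.CELL, 5.0, "P1")
        res = translation_search(mdl, xtal.observed, "P1")
        assert res.degenerate
        assert len(res.scores) == 1
        assert np.allclose(res.translations[0], 0.0)

    def test_p21_planted_translation_recovered(self, placed_model):
        planted = np.array([0.25, 0.0, 0.1])
        xtal = synth.make_crystal(
            placed_model, "P21", self.CELL, d=4.0, shift_frac=planted
        )
        mdl = synth.structure_factors_direct(placed_model, self.CELL, 4.0, "P1")
        res = translation_search(mdl, xtal.observed, "P21", n_grid=20)
        best = res.translations[0]
        # P21 origin freedom: solutions equivalent modulo (1/2, *, 1/2);
        # the dyad-axis component is unconstrained (set to 0 in the scan)
        dx = min(abs(best[0] - planted[0]) % 0.5, 0.5 - abs(best[0] - planted[0]) % 0.5)
        dz = min(abs(best[2] - planted[2]) % 0.5, 0.5 - abs(best[2] - planted[2]) % 0.5)
        assert dx <= 1.0 / 20 + 1e-9
        assert dz <= 1.0 / 20 + 1e-9
        assert res.scores[0] > 0.99

    def test_truth_beats_random_translations(self, placed_model):
        planted = np.array([0.25, 0.0, 0.1])
        xtal = synth.make_crystal(
            placed_model, "P21", self.CELL, d=5.0, shift_frac=planted
        )
        mdl = synth.structure_factors_direct(placed_model, self.CELL, 5.0, "P1")
        from hybridfit.em_mr import calculated_amplitudes

        def cc_at(t):
            calc = calculated_amplitudes(mdl, xtal.observed.hkl, "P21", t)
            ok = np.isfinite(calc)
            a = xtal.observed.amplitude[ok] - xtal.observed.amplitude[ok].mean()
            b = calc[ok] - calc[ok].mean()
            return a @ b / np.linalg.norm(a) / np.linalg.norm(b)

        truth_cc = cc_at(planted)
        rng = np.random.default_rng(9)
        for _ in range(20):
            assert truth_cc >= cc_at(rng.uniform(0, 1, 3))


class TestPhaseExtension:
    CELL = np.array([64.0, 64.0, 56.0])

    @pytest.fixture(scope="class")
    @staticmethod
    def crystal():
        model = synth.toy_complex()
        pos = model.transformed(
            np.eye(3), np.array([12.0, 12.0, 12.0]) - model.positions.min(axis=0)
        )
        return synth.make_crystal(pos, "P1", TestPhaseExtension.CELL, d=5.0)

    @staticmethod
    def _start_at(truth, d_start):
        low = truth.d >= d_start
        return PhaseSet(
            StructureFactorSet(
                truth.cell, "P1", truth.hkl[low], truth.amplitude[low], truth.phase[low]
            ),
            d_start,
        )

    def test_zero_cycles_is_fixed_point(self, crystal):
        start = self._start_at(crystal.truth, 10.0)
        out, diag = phase_extend(start, crystal.observed, 0.9, n_cycles=0)
        err = mean_phase_error(out, start)
        assert err < 1.0
        assert len(diag) == 0

    def test_extension_phases_much_better_than_random(self, crystal):
        start = self._start_at(crystal.truth, 10.0)
        out, diag = phase_extend(start, crystal.observed, 0.9, n_cycles=20)
        new = out.sf.d < 10.0
        newly = StructureFactorSet(
            out.sf.cell, "P1", out.sf.hkl[new], out.sf.amplitude[new], out.sf.phase[new]
        )
        err = mean_phase_error(newly, crystal.truth)
        assert err <= 60.0
        assert err <= 90.0 - 20.0

    def test_map_cc_improves_over_low_resolution_start(self, crystal):
        start = self._start_at(crystal.truth, 10.0)
        out, _ = phase_extend(start, crystal.observed, 0.9, n_cycles=20)
        shape = (32, 32, 28)
        truth_map = sf_to_map(crystal.truth, shape)
        start_map = sf_to_map(start.sf, shape)
        ext_map = sf_to_map(out.sf, shape)

        def cc(a, b):
            x = a.values.ravel() - a.values.mean()
            y = b.values.ravel() - b.values.mean()
            return x @ y / np.linalg.norm(x) / np.linalg.norm(y)

        assert cc(ext_map, truth_map) > cc(start_map, truth_map)

    def test_observed_amplitudes_pass_through_bit_exact(self, crystal):
        start = self._start_at(crystal.truth, 10.0)
        out, _ = phase_extend(start, crystal.observed, 0.9, n_cycles=20)
        table = {
            tuple(h): a
            for h, a in zip(map(tuple, crystal.observed.hkl), crystal.observed.amplitude)
        }
        for h, a in zip(map(tuple, out.sf.hkl), out.sf.amplitude):
            assert table[h] == a  # bit-exact


class TestMeanPhaseError:
    def _phased(self, phases, seed=0):
        rng = np.random.default_rng(seed)
        n = len(phases)
        hkl = np.stack([np.arange(1, n + 1), np.zeros(n, int), np.zeros(n, int)], axis=1)
        return StructureFactorSet(
            [100.0] * 3, "P1", hkl, rng.uniform(1, 2, n), np.asarray(phases, float)
        )

    def test_identity_zero_and_antiphase_180(self):
        a = self._phased([10.0, -50.0, 120.0])
        assert mean_phase_error(a, a) == 0.0
        b = self._phased([190.0, 130.0, -60.0])
        assert mean_phase_error(a, b) == pytest.approx(180.0)

    def test_random_phases_average_90(self):
        rng = np.random.default_rng(4)
        n = 2000
        a = self._phased(rng.uniform(-180, 180, n))
        b = self._phased(rng.uniform(-180, 180, n))
        # uniform independent differences: mean 90, sd 52/sqrt(n)
        assert abs(mean_phase_error(a, b) - 90.0) < 3 * 52.0 / np.sqrt(n)

    def test_no_common_reflections_error(self):
        a = self._phased([0.0])
        b = self._phased([0.0])
        b.hkl = b.hkl + 50
        with pytest.raises(ValueError):
            mean_phase_error(a, b)


class TestHKLIO:
    def test_round_trip_with_and_without_phases(self, tmp_path, random_map8):
        sf = resolution_filter(map_to_sf(random_map8), 4.0, 30.0)
        p = tmp_path / "a.hkl"
        write_hkl(sf, p)
        back = read_hkl(p)
        assert np.array_equal(back.hkl, sf.hkl)
        assert np.allclose(back.amplitude, sf.amplitude, rtol=1e-7)
        assert np.allclose(back.phase, sf.phase, atol=1e-5)
        q = tmp_path / "b.hkl"
        write_hkl(sf.amplitudes_only(), q)
        back2 = read_hkl(q)
        assert not back2.has_phases
        assert np.isnan(back2.phase).all()
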