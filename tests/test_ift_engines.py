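"""Hologram-retrieval engines: regularizations, apodization, feedback."""

import numpy as np
import pytest
from scipy.ndimage import binary_dilation

from aoholo.cli_io import make_fixture
from aoholo.field_model import ApertureSpec, aperture_slit
from aoholo.ift_engines import (
    DegenerateTargetError,
    Hologram1D,
    IFTConfig,
    MaskError,
    Target1D,
    apodize,
    decadic_gain,
    efficiency_1d,
    gs_complex,
    gs_dynamic,
    gs_extended,
    gs_static,
    inverse_decadic_gain,
    reconstruct_1d,
    with_freedom_domain,
)
from aoholo.metrics import speckle_noise, target_error


def _point_target(optics):
    n = optics.grid_size
    amp = np.zeros(n)
    amp[n // 2] = 1.0
    return Target1D(amp, amp > 0, length_um=optics.pitch_target_um)


class TestDecadicGain:
    @pytest.mark.parametrize("g,expected", [(0.0, 0.0), (0.9, 0.5), (0.99, 1.0)])
    def test_printed_values(self, g, expected):
        assert decadic_gain(g) == pytest.approx(expected, abs=1e-12)

    def test_roundtrip(self):
        g = np.linspace(0.0, 0.99, 23)
        assert np.max(np.abs(inverse_decadic_gain(decadic_gain(g)) - g)) < 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            decadic_gain(1.0)
        with pytest.raises(ValueError):
            decadic_gain(-0.1)
        with pytest.raises(ValueError):
            inverse_decadic_gain(-0.5)


class TestTargetValidation:
    def test_all_zero_target_rejected(self, optics):
        n = optics.grid_size
        with pytest.raises(DegenerateTargetError):
            Target1D(np.zeros(n), np.zeros(n, dtype=bool))

    def test_overlapping_masks_rejected(self, optics):
        n = optics.grid_size
        amp = np.zeros(n)
        amp[10] = 1.0
        with pytest.raises(MaskError):
            Target1D(amp, amp > 0, freedom_mask=amp > 0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            IFTConfig(iterations=0)
        with pytest.raises(ValueError):
            IFTConfig(am_gain=1.01)
        with pytest.raises(ValueError):
            IFTConfig(iterations=10, ramp_iterations=20)
        with pytest.raises(ValueError):
            IFTConfig(apod_gain=1.5)


class TestStaticEngine:
    def test_point_target_constant_phase_and_limited_spot(self, optics):
        h = gs_static(_point_target(optics), IFTConfig(iterations=50, seed=0), optics)
        slit = aperture_slit(optics) > 0
        ph = h.phase_unwrapped[slit]
        rel = np.angle(np.exp(1j * (ph - ph[ph.size // 2])))
        assert np.std(rel) < 1e-6  # flat phase modulo a global offset
        amp = reconstruct_1d(h).amplitude
        assert np.argmax(amp) == optics.grid_size // 2

    def test_three_point_reconstruction_has_ghosts_and_error(self, optics):
        t3 = make_fixture("three_point", optics)
        h = gs_static(t3, IFTConfig(seed=0), optics)
        amp = reconstruct_1d(h).amplitude
        far = ~binary_dilation(t3.target_mask, iterations=6)
        assert amp[far].max() > 0.05 * amp.max()  # ghost side lobes present
        assert h.final_error > 0.02

    def test_determinism_same_seed_bit_identical(self, optics):
        t = make_fixture("five_point", optics)
        h1 = gs_static(t, IFTConfig(seed=7), optics)
        h2 = gs_static(t, IFTConfig(seed=7), optics)
        assert np.array_equal(h1.phase_unwrapped, h2.phase_unwrapped)
        assert np.array_equal(h1.final_holo_amplitude, h2.final_holo_amplitude)
        h3 = gs_static(t, IFTConfig(seed=8), optics)
        assert not np.array_equal(h1.phase_unwrapped, h3.phase_unwrapped)

    def test_self_consistency_of_recorded_error(self, optics):
        t = make_fixture("five_point", optics)
        h = gs_static(t, IFTConfig(seed=3), optics)
        err = target_error(reconstruct_1d(h).amplitude, t)
        assert err == pytest.approx(h.final_error, abs=1e-12)

    def test_amplitude_mask_second_harmonic_of_phase(self, optics):
        # discrete point targets produce harmonic phase/amplitude structure;
        # the amplitude carries the second harmonic of the phase fundamental
        t3 = make_fixture("three_point", optics)
        h = gs_static(t3, IFTConfig(seed=0), optics)
        slit = aperture_slit(optics) > 0
        ph = h.phase_unwrapped[slit] - h.phase_unwrapped[slit].mean()
        kp = int(np.argmax(np.abs(np.fft.rfft(ph))[1:])) + 1
        a = h.final_holo_amplitude[slit]
        spa = np.abs(np.fft.rfft(a - a.mean()))
        assert spa[2 * kp] > 10 * np.median(spa)


class TestDynamicEngine:
    def test_empty_freedom_domain_matches_static(self, optics):
        t = make_fixture("five_point", optics)
        hs = gs_static(t, IFTConfig(seed=5), optics)
        hd = gs_dynamic(t, IFTConfig(seed=5, regularization="dynamic"), optics)
        assert np.array_equal(hs.phase_unwrapped, hd.phase_unwrapped)

    def test_point_amplitudes_more_homogeneous_than_static(self, optics):
        t = make_fixture("five_point", optics)
        idx = np.flatnonzero(t.amplitude)
        spread_s, spread_d = [], []
        for s in range(5):
            hs = gs_static(t, IFTConfig(seed=s), optics)
            hd = gs_dynamic(
                with_freedom_domain(t, 8), IFTConfig(seed=s, regularization="dynamic"), optics
            )
            ps = reconstruct_1d(hs).amplitude[idx]
            pd = reconstruct_1d(hd).amplitude[idx]
            spread_s.append(np.ptp(ps) / ps.mean())
            spread_d.append(np.ptp(pd) / pd.mean())
        assert np.mean(spread_d) < np.mean(spread_s)

    def test_dense_line_noise_relegated_to_freedom_domain(self, optics):
        # domain mixing: on-target speckle drops, off-target power grows
        line = make_fixture("line_8um", optics)
        lf = with_freedom_domain(line, 8)
        sp_s, sp_d, off_s, off_d = [], [], [], []
        for s in range(3):
            hs = gs_static(line, IFTConfig(seed=s), optics)
            hd = gs_dynamic(lf, IFTConfig(seed=s, regularization="dynamic"), optics)
            rs = reconstruct_1d(hs).amplitude
            rd = reconstruct_1d(hd).amplitude
            sp_s.append(speckle_noise(rs, line))
            sp_d.append(speckle_noise(rd, line))
            om = ~line.target_mask
            off_s.append(np.sum(rs[om] ** 2) / np.sum(rs**2))
            off_d.append(np.sum(rd[om] ** 2) / np.sum(rd**2))
        assert np.mean(sp_d) < np.mean(sp_s)
        assert np.mean(off_d) > np.mean(off_s)


class TestApodization:
    def test_gain_zero_is_pure_fm(self, optics):
        h = gs_static(make_fixture("three_point", optics), IFTConfig(seed=0), optics)
        a0 = apodize(h, 0.0)
        assert a0.mode == "FM"
        assert np.all(a0.amplitude_mask == 1.0)

    def test_full_gain_suppresses_ghost_spots(self, optics):
        t3 = make_fixture("three_point", optics)
        far = ~binary_dilation(t3.target_mask, iterations=6)
        for s in range(3):
            h = gs_static(t3, IFTConfig(seed=s), optics)
            r0 = reconstruct_1d(h).amplitude
            r1 = reconstruct_1d(apodize(h, 1.0)).amplitude
            assert r1[far].max() / r1.max() < r0[far].max() / r0.max()

    def test_efficiency_monotonically_decreasing_in_gain(self, optics):
        t5 = make_fixture("five_point", optics)
        gains = np.linspace(0, 1, 10)
        effs = []
        for g in gains:
            per_seed = [
                efficiency_1d(apodize(gs_static(t5, IFTConfig(seed=s), optics), g))
                for s in range(5)
            ]
            effs.append(np.mean(per_seed))
        assert effs[0] == pytest.approx(1.0)  # pure phase is lossless
        assert np.all(np.diff(effs) <= 1e-12)

    def test_gain_out_of_range_rejected(self, optics):
        h = gs_static(make_fixture("three_point", optics), IFTConfig(seed=0), optics)
        for g in (-0.1, 1.1):
            with pytest.raises(ValueError):
                apodize(h, g)

    def test_requires_retained_amplitude(self, optics):
        h = Hologram1D(np.zeros(optics.grid_size), np.ones(optics.grid_size), "FM", optics)
        with pytest.raises(ValueError):
            apodize(h, 0.5)


class TestComplexEngine:
    def test_point_target_flat_mask_and_phase(self, optics):
        h = gs_complex(
            _point_target(optics),
            IFTConfig(seed=0, regularization="complex", am_gain=0.99),
            optics,
        )
        assert h.mode == "FM/AM"
        slit = aperture_slit(optics) > 0
        assert h.amplitude_mask[slit].min() > 0.999  # feedback has nothing to correct
        ph = h.phase_unwrapped[slit]
        assert np.std(np.angle(np.exp(1j * (ph - ph[0])))) < 1e-6

    def test_speckle_decreases_with_feedback_gain(self, optics):
        line = make_fixture("line_8um", optics)
        means = []
        for g in (0.0, 0.9, 0.99):
            sp = []
            for s in range(5):
                h = gs_complex(
                    line, IFTConfig(seed=s, regularization="complex", am_gain=g), optics
                )
                sp.append(speckle_noise(reconstruct_1d(h).amplitude, line))
            means.append(np.mean(sp))
        assert means[0] > means[1] > means[2]

    def test_shaped_profiles_near_noise_free_at_full_gain(self, optics):
        for name in ("triangle", "parabola", "sinusoid"):
            t = make_fixture(name, optics)
            h = gs_complex(
                t, IFTConfig(seed=0, regularization="complex", am_gain=1.0), optics
            )
            assert speckle_noise(reconstruct_1d(h).amplitude, t) < 0.05

    def test_gain_above_one_rejected(self, optics):
        with pytest.raises(ValueError):
            IFTConfig(regularization="complex", am_gain=1.5)


class TestExtendedEngine:
    def test_point_target_flat_phase_like_plain(self, small_optics):
        t = _point_target(small_optics)
        cfg = IFTConfig(iterations=30, seed=0)
        he = gs_extended(t, ApertureSpec("circular", None), cfg, small_optics)
        slit = aperture_slit(small_optics) > 0
        ph = he.phase_unwrapped[slit]
        assert np.std(np.angle(np.exp(1j * (ph - ph[0])))) < 1e-6

    def test_square_aperture_falls_back_to_plain(self, small_optics):
        t = make_fixture("five_point", small_optics)
        cfg = IFTConfig(iterations=30, seed=2)
        with pytest.warns(UserWarning):
            hs = gs_extended(t, ApertureSpec("square", None), cfg, small_optics)
        hp = gs_static(t, cfg, small_optics)
        assert np.array_equal(hs.phase_unwrapped, hp.phase_unwrapped)

    def test_extended_hologram_forward_model_self_consistency(self, small_optics):
        line = make_fixture("line_8um", small_optics)
        cfg = IFTConfig(iterations=40, seed=1, regularization="complex", am_gain=0.99)
        he = gs_extended(line, ApertureSpec("circular", None), cfg, small_optics)
        err = target_error(reconstruct_1d(he).amplitude, line)
        assert err == pytest.approx(he.final_error, abs=1e-12)
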