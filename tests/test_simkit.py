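"""Generator contracts: kinetics, rendering, determinism, calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import synflux as sf
from synflux import simkit
from synflux.simkit import (
    _draw_pool_fractions,
    _lognormal_mean,
    _psf_stamp,
    syphy_unquenched_fraction,
)


class TestSypHyKinetics:
    def test_no_release_case(self, syphy_prot):
        u = syphy_unquenched_fraction(0.0, 0.0, syphy_prot)
        nh = syphy_prot.sl(syphy_prot.nh4cl_frames)
        assert np.all(u[:nh.start] == 0.0)
        assert np.all(u[nh] == 1.0)

    def test_ctrl_window_means_are_analytic(self, ctrl, syphy_prot):
        """Noise-free CTRL kinetics sit on exact plateaus inside the
        RRP and TRP analysis windows."""
        u = sf.syphy_punctum_trace(ctrl, syphy_prot, noise_free=True)
        assert u[syphy_prot.sl(syphy_prot.rrp_window)].mean() == \
            pytest.approx(0.13, abs=1e-9)
        assert u[syphy_prot.sl(syphy_prot.trp_window)].mean() == \
            pytest.approx(0.61, abs=1e-9)

    @given(f_rrp=st.floats(0.0, 0.5), extra=st.floats(0.0, 0.5))
    def test_bafilomycin_monotonicity(self, f_rrp, extra):
        """The cumulative (bafilomycin) contract: u never decreases and
        ends at exactly 1 in the NH4Cl window."""
        prot = sf.syphy_protocol()
        u = syphy_unquenched_fraction(f_rrp, f_rrp + extra, prot)
        assert np.all(np.diff(u) >= -1e-12)
        assert u[-1] == 1.0

    def test_missing_nh4cl_window_is_an_error(self, ctrl):
        prot = sf.syphy_protocol()
        prot.nh4cl_frames = None
        with pytest.raises(ValueError, match="NH4Cl"):
            sf.syphy_punctum_trace(ctrl, prot)


class TestRendering:
    def _single_punctum_truth(self, brightness=500.0, bg=10.0, tau=None):
        return simkit.GroundTruth(
            modality="syphy", centers=[(32.0, 32.0)], brightness=[brightness],
            background_level=bg, bleach_tau=tau,
        )

    def _nf_cfg(self, **kw):
        base = dict(shape=(64, 64), n_puncta=(1, 1), poisson=False,
                    read_noise_sigma=0.0, bleach_tau_frames=None)
        base.update(kw)
        return simkit.SimConfig(**base)

    def test_static_source_psf_mass(self):
        truth = self._single_punctum_truth()
        cfg = self._nf_cfg()
        stack = simkit.render_stack(truth, np.ones(5), cfg)
        assert np.allclose(stack.data, stack.data[0])   # frame-wise identical
        stamp, _ = _psf_stamp(cfg.psf_sigma)
        fg = stack.data[0].sum() - 10.0 * 64 * 64
        assert fg == pytest.approx(500.0 * stamp.sum(), rel=1e-6)

    def test_bleach_is_exponential_by_construction(self):
        T = 40
        truth = self._single_punctum_truth(tau=float(T))
        stack = simkit.render_stack(truth, np.ones(T + 1), self._nf_cfg())
        fg = stack.data.sum(axis=(1, 2)) - 10.0 * 64 * 64
        assert fg[T] / fg[0] == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_same_seed_gives_bit_identical_stacks(self, ctrl):
        cfg = sf.default_config("syphy", shape=(64, 64), n_puncta=(5, 8))
        a, ta, _ = simkit.simulate_recording("syphy", ctrl, cfg=cfg, seed=11)
        b, tb, _ = simkit.simulate_recording("syphy", ctrl, cfg=cfg, seed=11)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(ta.centers, tb.centers)

    def test_saturating_punctum_is_named(self):
        truth = self._single_punctum_truth(brightness=70000.0)
        with pytest.raises(ValueError, match="punctum 0"):
            simkit.render_stack(truth, np.ones(3), self._nf_cfg())

    def test_nostim_field_matches_stimulated_field(self, ctrl):
        cfg = sf.default_config("syphy", shape=(64, 64), n_puncta=(5, 8))
        _, ta, _ = simkit.simulate_recording("syphy", ctrl, cfg=cfg, seed=4)
        _, tb, _ = simkit.simulate_recording("syphy_nostim", ctrl, cfg=cfg, seed=4)
        np.testing.assert_array_equal(ta.centers, tb.centers)
        np.testing.assert_array_equal(ta.brightness, tb.brightness)

    def test_nostim_frame_mean_non_increasing_and_tau_recoverable(self, ctrl):
        """A no-stimulation movie decays by bleaching only; an exponential
        fit to its noise-free punctum trace recovers the bleaching time
        constant within 10%."""
        cfg = sf.default_config("syphy", shape=(96, 96), n_puncta=(20, 25))
        stack, truth, prot = simkit.simulate_recording(
            "syphy_nostim", ctrl, cfg=cfg, seed=9)
        fm = stack.data.mean(axis=(1, 2))
        # smoothed frame-mean trend decreases (up to noise)
        k = 30
        coarse = fm[:len(fm) // k * k].reshape(-1, k).mean(axis=1)
        assert np.all(np.diff(coarse) < 0)
        pset = sf.extract_traces(stack, truth.centers, 3.0)
        trace = sf.mean_trace(pset) - sf.estimate_background(stack, pset)
        from synflux.pools import fit_bleach_tau
        tau = fit_bleach_tau(trace)
        assert tau == pytest.approx(truth.bleach_tau, rel=0.10)


class TestEnsembleCalibration:
    def test_pool_fraction_draws_center_on_preset_means(self, ctrl):
        rng = np.random.default_rng(123)
        draws = np.array([_draw_pool_fractions(ctrl, rng) for _ in range(300)])
        for j, (mean, cv) in enumerate([(0.13, ctrl.cv("f_rrp")),
                                        (0.61, ctrl.cv("f_trp"))]):
            se = mean * cv / np.sqrt(300)
            assert abs(draws[:, j].mean() - mean) < 2 * se
        assert np.all(draws[:, 0] <= draws[:, 1])   # pool ordering per draw

    def test_lognormal_mean_parameterization_is_exact(self):
        rng = np.random.default_rng(7)
        x = _lognormal_mean(rng, 1.13, 0.2, 20000)
        assert x.mean() == pytest.approx(1.13, rel=0.01)
        assert x.std() / x.mean() == pytest.approx(0.2, rel=0.05)

    def test_iglusnfr_ground_truth_ppr_centers_on_preset(self, ctrl):
        """Monte-Carlo mean of per-recording ground-truth PPR over many
        seeds approaches the preset mean within 2 SEM."""
        n = 150
        rng_draws = []
        for s in range(n):
            frng = simkit._field_rng(s)
            _lognormal_mean(frng, ctrl.glu_p1_scale, ctrl.cv("glu_p1"))
            rng_draws.append(_lognormal_mean(frng, ctrl.ppr_mu, ctrl.cv("ppr")))
        m = np.mean(rng_draws)
        sem = ctrl.ppr_mu * ctrl.cv("ppr") / np.sqrt(n)
        assert abs(m - ctrl.ppr_mu) < 2 * sem


class TestIccGenerator:
    def test_noise_free_field_is_exact(self, ctrl):
        cfg = simkit.IccConfig(poisson=False, read_noise_sigma=0.0)
        _, _, _, truth = sf.simulate_icc_image(ctrl, cfg=cfg, seed=1)
        means = truth.per_punctum["true_mean"]
        assert np.mean(means) == pytest.approx(cfg.pcreb_ctrl_level, rel=0.01)

    def test_dmt_to_ctrl_truth_ratio(self):
        """Over many simulated fields the ground-truth nuclear level of
        the DMT preset is ~2.13x the control level (within 2 SE of the
        generator's own dispersion)."""
        n = 80
        means = {}
        for cond in ("CTRL", "DMT"):
            p = sf.make_preset(cond)
            level = [sf.simulate_icc_image(p, seed=s)[3].params["field_level"]
                     for s in range(n)]
            means[cond] = (np.mean(level), np.std(level) / np.sqrt(n))
        ratio = means["DMT"][0] / means["CTRL"][0]
        se = ratio * np.hypot(means["DMT"][1] / means["DMT"][0],
                              means["CTRL"][1] / means["CTRL"][0])
        assert abs(ratio - 2.13) < 2 * se

    def test_non_neuronal_nuclei_flagged(self):
        p = sf.make_preset("CTRL")
        for s in range(6):
            _, _, _, truth = sf.simulate_icc_image(p, seed=s)
            neuronal = truth.per_punctum["neuronal"]
            if not neuronal.all():
                assert neuronal.dtype == bool
                return
        pytest.fail("no field with non-neuronal nuclei in 6 seeds")

    def test_unplaceable_nuclei_error(self, ctrl):
        cfg = simkit.IccConfig(shape=(64, 64), min_separation=60.0)
        with pytest.raises(RuntimeError, match="nuclei"):
            sf.simulate_icc_image(ctrl, cfg=cfg, seed=0)


def test_unknown_modality_rejected(ctrl):
    with pytest.raises(ValueError, match="modality"):
        simkit.simulate_recording("fura2", ctrl, seed=0)


def test_mismatched_protocol_rejected(ctrl):
    with pytest.raises(ValueError, match="paired-pulse"):
        simkit.simulate_recording("iglusnfr", ctrl, seed=0,
                                  protocol=sf.syphy_protocol())
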