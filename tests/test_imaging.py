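"""Rendering, photobleaching and the phototoxicity reporter."""

import dataclasses

import numpy as np
import pytest

import calsense as cs
from calsense.imaging import (ImagingParams, apply_bleaching, render_frame,
                              render_stack, ros_response, write_stack)
from calsense.kinetics import CellState, Chamber
from calsense.protocols import make_protocol


def make_cell(x=20.0, y=20.0, area=2.0, fluor=400.0, cid=1):
    return CellState(cell_id=cid, parent_id=None, birth_time=0.0, area=area,
                     calcein=fluor * area, x=x, y=y, theta=0.3)


class TestRenderFrame:
    def test_empty_chamber_is_background(self):
        params = ImagingParams()
        rng = np.random.default_rng(0)
        fluor, phase, labels = render_frame([], {}, params, Chamber(), rng)
        assert labels.max() == 0
        assert abs(fluor.mean() - params.background_au) < 3 * params.noise_sd
        assert abs(phase.mean() - params.phase_background_au) \
            < 3 * params.phase_noise_sd

    def test_noiseless_render_is_exact_over_the_mask(self):
        """With no noise and no blur, the mean pixel value over a cell's
        mask equals gain x concentration + background exactly."""
        params = ImagingParams(noise_sd=0.0, psf_sigma_px=0.0,
                               phase_noise_sd=0.0)
        rng = np.random.default_rng(0)
        cell = make_cell(fluor=333.0)
        fluor, _, labels = render_frame([cell], {}, params, Chamber(), rng)
        mask = labels == cell.cell_id
        assert mask.sum() > 100
        expected = params.gain_au_per_conc * cell.mean_fluor \
            + params.background_au
        assert fluor[mask].mean() == pytest.approx(expected, rel=1e-9)

    def test_rendered_area_matches_rod_geometry(self):
        params = ImagingParams(noise_sd=0.0, psf_sigma_px=0.0)
        rng = np.random.default_rng(0)
        cell = make_cell(area=2.0)
        _, _, labels = render_frame([cell], {}, params, Chamber(), rng)
        px_area = (labels == 1).sum() * params.pixel_size ** 2
        assert px_area == pytest.approx(2.0, rel=0.10)

    def test_cell_outside_chamber_rejected(self):
        params = ImagingParams()
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="outside"):
            render_frame([make_cell(x=55.0)], {}, params, Chamber(), rng)

    def test_extracellular_sites_painted_into_strips(self):
        params = ImagingParams(noise_sd=0.0, psf_sigma_px=0.0)
        rng = np.random.default_rng(0)
        sig = {"supply_channel": 30.0, "chamber_entrance": 2.0,
               "cell_proximity": 1.0}
        fluor, _, _ = render_frame([], sig, params, Chamber(), rng)
        assert fluor[5, 5] == pytest.approx(params.background_au + 30.0)
        assert fluor[50, 5] == pytest.approx(params.background_au + 2.0)
        assert fluor[200, 5] == pytest.approx(params.background_au + 1.0)


class TestRoundTrip:
    def test_measured_concentration_recovers_ground_truth(self, params,
                                                          imaging_params,
                                                          tmp_path):
        """Render -> measure with ground-truth masks recovers each
        cell's concentration within 2% at default noise (systematic
        PSF edge loss corrected by comparing to the noiseless render)."""
        from calsense import quant

        col = cs.simulate_colony(3, params,
                                 make_protocol("reference_cgxii",
                                               duration=80.0),
                                 seed=7)
        stack = render_stack(col, imaging_params, seed=8, bleach=False)
        clean = render_stack(
            col, dataclasses.replace(imaging_params, noise_sd=0.0,
                                     phase_noise_sd=0.0),
            seed=8, bleach=False)
        noisy, _, _ = quant.measure_stack(stack, bypass_ground_truth=True,
                                          return_masks=True)
        ref, _, _ = quant.measure_stack(clean, bypass_ground_truth=True,
                                        return_masks=True)
        merged = noisy.merge(ref, on=["frame", "label"],
                             suffixes=("", "_ref"))
        rel = np.abs(merged.mean_fluor_au - merged.mean_fluor_au_ref) \
            / merged.mean_fluor_au_ref
        assert rel.max() < 0.02

        write_stack(stack, tmp_path / "stk")
        back = quant.read_stack(tmp_path / "stk")
        assert np.array_equal(back.fluor, stack.fluor)
        assert np.array_equal(back.labels, stack.labels)
        assert np.allclose(back.timestamps, stack.timestamps)
        assert back.site_regions == stack.site_regions


class TestBleaching:
    def test_zero_fraction_is_identity(self, famine_colony):
        params = ImagingParams(bleach_frac_per_exposure=0.0)
        out = apply_bleaching(famine_colony, params)
        for fa, fb in zip(famine_colony.frames, out.frames):
            for ca, cb in zip(fa, fb):
                assert ca.calcein == cb.calcein

    def test_geometric_decay_of_arrested_cell(self, params):
        """0.002 loss per exposure over 100 exposed frames leaves
        calcein at initial x 0.998^100."""
        prot = make_protocol("reference_cgxii", duration=800.0, cam_conc=0.0,
                             phase_overrides=dict(carbon_present=False))
        p = dataclasses.replace(params, lysis_rate=0.0, p_dark=0.0,
                                famine_division_rate=0.0, cell_cv=0.0)
        col = cs.simulate_colony(1, p, prot, seed=3, founder_fluor=500.0,
                                 relax_geometry=False)
        ip = ImagingParams(bleach_frac_per_exposure=0.002)
        out = apply_bleaching(col, ip)
        # attenuation relative to the unbleached trajectory is exactly
        # geometric in the number of exposures (frames 0..100 incl.)
        att0 = out.frames[0][0].calcein / col.frames[0][0].calcein
        att100 = out.frames[100][0].calcein / col.frames[100][0].calcein
        assert att100 / att0 == pytest.approx(0.998 ** 100, rel=1e-9)
        # bleached amount is logged for mass balance
        c = out.frames[100][0]
        assert c.cum_bleached == pytest.approx(
            col.frames[100][0].calcein - c.calcein, rel=1e-9)

    def test_sparse_exposure_reduces_loss_proportionally(self, params):
        prot = make_protocol("reference_cgxii", duration=800.0, cam_conc=0.0,
                             phase_overrides=dict(carbon_present=False))
        p = dataclasses.replace(params, lysis_rate=0.0, p_dark=0.0,
                                famine_division_rate=0.0, cell_cv=0.0)
        col = cs.simulate_colony(1, p, prot, seed=3, founder_fluor=500.0,
                                 relax_geometry=False)
        every = apply_bleaching(col, ImagingParams(
            bleach_frac_per_exposure=0.0015))
        sixth = apply_bleaching(col, ImagingParams(
            bleach_frac_per_exposure=0.0015, exposure_every=6))
        n = 96
        att_every = every.frames[n][0].calcein / col.frames[n][0].calcein
        att_sixth = sixth.frames[n][0].calcein / col.frames[n][0].calcein
        # frames 0..96: 97 exposures on the dense schedule, 17 on the
        # every-6th schedule (frames 0, 6, ..., 96)
        assert att_every == pytest.approx(0.9985 ** 97, rel=1e-9)
        assert att_sixth == pytest.approx(0.9985 ** 17, rel=1e-9)
        assert (1 - att_sixth) == pytest.approx((1 - att_every) / 6,
                                                rel=0.15)

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            ImagingParams(bleach_frac_per_exposure=0.05)


class TestRosReporter:
    def test_below_threshold_basal_and_growing(self):
        p = ImagingParams(ros_mode="reporter")
        sig, arrested = ros_response(0.0, p)
        assert sig == p.ros_basal_au and not arrested

    def test_above_threshold_elevated_and_arrested(self):
        p = ImagingParams(ros_mode="reporter")
        sig, arrested = ros_response(2.0 * p.ros_dose_threshold, p)
        assert sig > p.ros_basal_au and arrested

    def test_signal_monotone_in_dose(self):
        p = ImagingParams(ros_mode="reporter")
        doses = np.linspace(0.0, 5.0, 40)
        sigs = [ros_response(d, p)[0] for d in doses]
        assert np.all(np.diff(sigs) >= 0.0)

    def test_requires_reporter_mode(self):
        with pytest.raises(ValueError):
            ros_response(1.0, ImagingParams())
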