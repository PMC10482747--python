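"""Virtual-extensometer, Poisson-ratio and synchronization behaviour.

These tests feed the extensometers analytic displacement fields (the
generator's closed form sampled at the subset centres), isolating them from
the correlation engine.
"""

import numpy as np
import pytest

from conftest import make_fields
from tensiledic import SpecimenGeometry, dic, extensometry
from tensiledic import synthetic as syn
from tensiledic.errors import InvalidArgumentError

GEOM = SpecimenGeometry(gauge_length_mm=8.5, gap_width_mm=20.0, width0_mm=8.0, thickness0_mm=4.0)
PIXEL_SCALE = 0.05


@pytest.fixture(scope="module")
def grid():
    # 512x256 image; ROI comfortably containing gauge (170 px) and width (160 px)
    return dic.build_grid((512, 256), (130, 382, 20, 236), subset_size=21, step=12,
                          search_margin=5)


def fields_for(grid, schedule, n_frames=6):
    pat = syn.SpecklePattern(
        image=np.zeros((512, 256), dtype=np.uint8),
        pixel_scale=PIXEL_SCALE, dot_density=0.0, dot_radius_range=(1, 1), seed=0,
    )
    t0, t1 = schedule.span
    times = np.linspace(t0, t1, n_frames)
    return make_fields(grid, pat, schedule, times)


class TestPlacement:
    def test_gauge_anchor_separation_is_h0(self, grid):
        exts = extensometry.place_extensometers(grid, GEOM, PIXEL_SCALE)
        gauge = exts[0]
        dy = gauge.points_b[:, 0].mean() - gauge.points_a[:, 0].mean()
        assert dy == pytest.approx(8.5 / PIXEL_SCALE)  # 170 px

    def test_crack_anchor_separation_default_3mm(self, grid):
        crack = extensometry.place_extensometers(grid, GEOM, PIXEL_SCALE)[1]
        dy = crack.points_b[:, 0].mean() - crack.points_a[:, 0].mean()
        assert dy == pytest.approx(3.0 / PIXEL_SCALE)
        assert crack.nominal_length_mm == 3.0

    def test_transverse_spans_initial_width(self, grid):
        trans = extensometry.place_extensometers(grid, GEOM, PIXEL_SCALE)[2]
        dx = trans.points_b[:, 1].mean() - trans.points_a[:, 1].mean()
        assert dx == pytest.approx(GEOM.width0_mm / PIXEL_SCALE)
        assert trans.nominal_length_mm == GEOM.width0_mm

    def test_gauge_outside_roi_rejected(self, grid):
        big = SpecimenGeometry(gauge_length_mm=19.0, gap_width_mm=25.0,
                               width0_mm=8.0, thickness0_mm=4.0)
        with pytest.raises(InvalidArgumentError):
            extensometry.place_extensometers(grid, big, PIXEL_SCALE)


class TestMeasureDistance:
    def test_identity_sequence_constant_nominal(self, grid):
        sched = syn.DeformationSchedule.ramp(1.0, 0.0, poisson=0.0)
        fields = fields_for(grid, sched)
        for ext in extensometry.place_extensometers(grid, GEOM, PIXEL_SCALE):
            series = extensometry.measure_distance(ext, fields, PIXEL_SCALE)
            assert np.allclose(series.distance_mm, ext.nominal_length_mm, atol=1e-9)

    def test_uniform_stretch_gauge_distance(self, grid):
        # lambda = 1.2 on h0 = 8.5 mm -> 10.2 mm
        sched = syn.DeformationSchedule.ramp(1.0, np.log(1.2), poisson=0.3)
        fields = fields_for(grid, sched)
        gauge = extensometry.place_extensometers(grid, GEOM, PIXEL_SCALE)[0]
        series = extensometry.measure_distance(gauge, fields, PIXEL_SCALE)
        assert series.distance_mm[-1] == pytest.approx(10.2, abs=0.02)

    def test_crack_decomposition(self, grid):
        # gauge extension = elastic extension + crack opening (Fig.-1-style
        # decomposition); the crack extensometer isolates the opening
        n_samples = 48
        times = np.linspace(0, 2.0, n_samples)
        opening = np.where(times >= 1.0, 0.8 * (times - 1.0), 0.0)
        crack = syn.CrackSchedule(onset_s=1.0, position_mm=0.0, opening_mm=opening)
        eps_max = 0.05
        sched = syn.DeformationSchedule(
            times=times,
            axial_stretch=np.exp(np.linspace(0, eps_max, n_samples)),
            poisson=np.full(n_samples, 0.3),
            crack=crack,
        )
        fields = fields_for(grid, sched, n_frames=9)
        exts = extensometry.place_extensometers(grid, GEOM, PIXEL_SCALE)
        gauge_d = extensometry.measure_distance(exts[0], fields, PIXEL_SCALE)
        crack_d = extensometry.measure_distance(exts[1], fields, PIXEL_SCALE)
        t_end = fields.frame_times[-1]
        lam_end = sched.stretch_at(float(t_end))
        open_end = sched.opening_at(float(t_end))
        # crack extensometer: its own elastic share plus the full opening
        assert crack_d.distance_mm[-1] == pytest.approx(
            3.0 * lam_end + open_end, abs=0.05
        )
        # difference from the gauge = elastic extension outside the crack zone
        outside = gauge_d.distance_mm[-1] - crack_d.distance_mm[-1]
        assert outside == pytest.approx((8.5 - 3.0) * lam_end, abs=0.05)


class TestPoisson:
    def make_series(self, eps_axial, nu):
        h = 8.5 * np.exp(eps_axial)
        w = 8.0 * np.exp(-nu * eps_axial)
        t = np.arange(len(eps_axial), dtype=float)
        axial = extensometry.DistanceSeries(t, h, "dic_gauge", 8.5)
        trans = extensometry.DistanceSeries(t, w, "dic_transverse", 8.0)
        return axial, trans

    def test_incompressible_contraction_gives_half(self):
        eps = np.linspace(0, 0.2, 21)
        axial, trans = self.make_series(eps, 0.5)
        traj = extensometry.poisson_trajectory(axial, trans)
        assert np.allclose(traj.ratio, 0.5, atol=1e-12)

    def test_zero_transverse_strain_gives_zero(self):
        eps = np.linspace(0, 0.2, 21)
        axial, trans = self.make_series(eps, 0.0)
        traj = extensometry.poisson_trajectory(axial, trans)
        assert np.allclose(traj.ratio, 0.0, atol=1e-12)

    def test_strain_floor_omits_near_zero_frames(self):
        eps = np.linspace(0, 0.02, 21)
        axial, trans = self.make_series(eps, 0.3)
        traj = extensometry.poisson_trajectory(axial, trans, strain_floor=0.005)
        assert traj.axial_true_strain.min() > 0.005
        assert len(traj.ratio) < len(eps)

    @pytest.mark.parametrize("nu", [0.1, 0.3, 0.5])
    def test_constant_ratio_recovery_from_fields(self, grid, nu):
        # closed-loop through extensometers: bias < 0.02 at axial strain 0.1
        sched = syn.DeformationSchedule.ramp(1.0, 0.1, poisson=nu)
        fields = fields_for(grid, sched, n_frames=11)
        exts = extensometry.place_extensometers(grid, GEOM, PIXEL_SCALE)
        axial = extensometry.measure_distance(exts[0], fields, PIXEL_SCALE)
        trans = extensometry.measure_distance(exts[2], fields, PIXEL_SCALE)
        traj = extensometry.poisson_trajectory(axial, trans)
        assert abs(traj.ratio[-1] - nu) < 0.02

    def test_sanity_band_flagging(self):
        eps = np.linspace(0, 0.2, 11)
        h = 8.5 * np.exp(eps)
        w = 8.0 * np.exp(+0.3 * eps)  # expanding width: nu = -0.3
        t = np.arange(11, dtype=float)
        axial = extensometry.DistanceSeries(t, h, "dic_gauge", 8.5)
        trans = extensometry.DistanceSeries(t, w, "dic_transverse", 8.0)
        traj = extensometry.poisson_trajectory(axial, trans)
        assert traj.flagged.all()


class TestSynchronize:
    def make_trace(self, slippage=None, time_offset=0.0):
        geom = GEOM
        sched = syn.DeformationSchedule.ramp(10.0, 0.2, rate_mode="stretch")
        arch = syn.MaterialArchetype(label="isotropic", peak_force_n=10.0)
        return syn.gen_force_trace(
            arch, geom, sched, sampling_rate_hz=500.0,
            slippage=slippage, time_offset_s=time_offset,
        )

    def test_identical_time_base_passthrough(self):
        trace = self.make_trace()
        out = extensometry.synchronize(trace.time_s, trace)
        assert np.allclose(out["force_n"].to_numpy(), trace.force_n)

    def test_frame_count_at_25fps_over_10s(self):
        trace = self.make_trace()
        frames = np.arange(0, 10.0 + 1e-9, 1 / 25.0)
        out = extensometry.synchronize(frames, trace)
        assert len(out) == 251

    def test_known_offset_recovers_peak_frame(self):
        offset = 0.2
        trace = self.make_trace(time_offset=offset)
        frames = np.arange(0, 10.0, 1 / 25.0)
        out = extensometry.synchronize(frames, trace, time_offset_s=offset)
        peak_time_camera = trace.time_s[trace.force_n.argmax()] - offset
        peak_frame = int(out["force_n"].to_numpy().argmax())
        assert abs(out["time_s"].iloc[peak_frame] - peak_time_camera) <= 1 / 25.0

    def test_disjoint_spans_rejected(self):
        trace = self.make_trace()
        with pytest.raises(InvalidArgumentError):
            extensometry.synchronize(np.array([100.0, 101.0]), trace)

    def test_machine_distance_dominates_after_slippage(self):
        # grip slippage adds machine travel the specimen never sees
        trace = self.make_trace(slippage=(2.0, 0.05))
        frames = np.arange(0, 10.0, 1 / 25.0)
        out = extensometry.synchronize(frames, trace)
        sched = syn.DeformationSchedule.ramp(10.0, 0.2, rate_mode="stretch")
        dic_gauge = np.array([8.5 * sched.stretch_at(t) for t in out["time_s"]])
        machine_h = 8.5 + out["machine_distance_mm"].to_numpy()
        after = out["time_s"].to_numpy() > 2.0
        assert np.all(machine_h[after] >= dic_gauge[after])
        assert np.all(np.abs(machine_h[~after] - dic_gauge[~after]) < 1e-9)
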