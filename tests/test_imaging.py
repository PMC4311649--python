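"""Silhouette extraction, meniscus location, tip tracking, bending angle."""

import math

import numpy as np
import pytest
from scipy import ndimage

from capadh.errors import (
    BaselineDetectionError,
    DataError,
    ThresholdingError,
)
from capadh.geometry import profile_eval
from capadh.imaging import (
    Frame,
    extract_silhouette,
    load_sequence,
    locate_fiber_tip,
    locate_meniscus,
    measure_bending_angle,
    read_manual_points,
    track_tip,
)
from capadh.pipeline import write_sequence
from capadh.synthetic import (
    CameraModel,
    MeniscusFamily,
    SyntheticTruth,
    render_frames,
)


def make_frame(img, scale=2e-6, stage=0.0, t=0.0):
    return Frame(image=np.asarray(img), timestamp=t, stage_position=stage,
                 pixel_scale=scale)


def disk_image(shape=(120, 160), center=(60.0, 80.0), radius=30.0,
               blur=0.0, noise=0.0, rng=None):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    img = np.where((rr - center[0]) ** 2 + (cc - center[1]) ** 2
                   <= radius**2, 0.0, 255.0)
    if blur > 0:
        img = ndimage.gaussian_filter(img, blur)
    if noise > 0:
        img = img + (rng or np.random.default_rng(0)).normal(0, noise,
                                                             img.shape)
    return np.clip(img, 0, 255)


class TestExtractSilhouette:
    @pytest.mark.parametrize("blur,noise", [(0.0, 0.0), (1.0, 5.0)])
    def test_disk_boundary_recovered(self, blur, noise):
        """A hard-rasterized binary disk pins the boundary to within one
        pixel everywhere; once the edge is area-sampled by optical blur the
        threshold interpolation becomes genuinely subpixel (RMS < 0.5 px)
        even with noise."""
        frame = make_frame(disk_image(blur=blur, noise=noise))
        sil = extract_silhouette(frame)
        pts_px = np.column_stack([
            sil.edge_points[:, 0] / frame.pixel_scale,
            frame.n_rows - 1 - sil.edge_points[:, 1] / frame.pixel_scale,
        ])  # back to (col, row)
        r = np.hypot(pts_px[:, 1] - 60.0, pts_px[:, 0] - 80.0)
        assert np.abs(r - 30.0).max() < 1.0
        if blur > 0:
            assert float(np.sqrt(np.mean((r - 30.0) ** 2))) < 0.5

    def test_uniform_image_rejected(self):
        with pytest.raises(ThresholdingError):
            extract_silhouette(make_frame(np.full((50, 50), 128.0)))

    def test_fixed_threshold_bypasses_bimodality(self):
        frame = make_frame(np.full((50, 50), 128.0))
        sil = extract_silhouette(frame, threshold=100.0)
        assert not sil.mask.any()


class TestLocateMeniscus:
    def test_flanks_on_true_meridian(self, rendered_experiment):
        frames, tseq, rec, _seq = rendered_experiment
        i = tseq.snap_index
        truth = tseq.frames[i].fit.profile
        sil = extract_silhouette(frames[i])
        loc = locate_meniscus(sil)
        assert loc.connected
        assert loc.r_tip == pytest.approx(truth.r_tip,
                                          abs=0.5 * frames[i].pixel_scale)
        axis_true = (frames[i].n_cols - 1) / 2 * frames[i].pixel_scale
        assert loc.axis_x == pytest.approx(axis_true,
                                           abs=1.0 * frames[i].pixel_scale)
        x = np.abs(loc.flank_points[:, 0] - axis_true)
        inside = (x > truth.r_tip) & (x < truth.a * 0.999)
        resid = loc.flank_points[inside, 1] - profile_eval(truth, x[inside])
        # vertical residual of a steep flank is slope-amplified; compare the
        # normal distance against the half-pixel localization bound
        slope = np.abs(truth.b * x[inside] / (
            truth.a**2 * np.sqrt(1 - (x[inside] / truth.a) ** 2)))
        normal = resid / np.hypot(1.0, slope)
        assert np.sqrt(np.mean(normal**2)) < 0.5 * frames[i].pixel_scale

    def test_flat_surface_has_no_flanks(self):
        truth = SyntheticTruth(seed=11)
        frames, tseq, _ = render_frames(truth, 4)
        post = frames[-1]  # relaxed frame: flat bath + free fiber
        loc = locate_meniscus(extract_silhouette(post))
        assert not loc.connected
        assert len(loc.flank_points) == 0
        base_true = post.y_of_row(round(0.72 * post.n_rows))
        assert loc.baseline_y == pytest.approx(base_true,
                                               abs=0.5 * post.pixel_scale)

    def test_meniscus_wider_than_field_of_view(self):
        # dark region rising from the bath touches both frame sides
        img = np.full((80, 100), 255.0)
        img[50:, :] = 0.0  # bath
        rr, cc = np.mgrid[:80, :100]
        img[(rr > 20) & (rr + np.abs(cc - 50) / 3 > 45)] = 0.0
        img[:, 48:53] = 0.0  # fiber
        with pytest.raises(BaselineDetectionError):
            locate_meniscus(extract_silhouette(make_frame(img),))

    def test_fiber_tip_in_relaxed_frame(self):
        truth = SyntheticTruth(seed=11)
        frames, tseq, _ = render_frames(truth, 4)
        tip = locate_fiber_tip(extract_silhouette(frames[-1]))
        assert tip == pytest.approx(
            tseq.frames[-1].tip_position
            + frames[-1].y_of_row(round(0.72 * frames[-1].n_rows)),
            abs=0.5 * frames[-1].pixel_scale,
        )


class TestTrackTip:
    @staticmethod
    def textured_frame(shift=0.0, scale=2e-6, rng_seed=5):
        rng = np.random.default_rng(rng_seed)
        base = ndimage.gaussian_filter(rng.random((200, 120)) * 255, 3)
        img = ndimage.shift(base, (shift, 0.0), order=3, mode="nearest")
        return make_frame(img, scale=scale)

    def test_identical_frames_zero_displacement(self):
        frames = [self.textured_frame() for _ in range(3)]
        pos = track_tip(frames, (40, 90, 30, 90))
        assert np.allclose(pos - pos[0], 0.0, atol=1e-12)

    def test_integer_shift(self):
        frames = [self.textured_frame(0.0), self.textured_frame(5.0)]
        pos = track_tip(frames, (40, 90, 30, 90))
        # image content moved down 5 px -> physical tip moved down 10 um
        assert pos[1] - pos[0] == pytest.approx(-10e-6, abs=0.3e-6)

    def test_subpixel_shifts(self):
        rng = np.random.default_rng(9)
        errs = []
        for _ in range(30):
            s = rng.uniform(-0.3, 0.3)
            frames = [self.textured_frame(0.0), self.textured_frame(s)]
            pos = track_tip(frames, (40, 90, 30, 90))
            errs.append((pos[0] - pos[1]) / 2e-6 - s)
        assert np.sqrt(np.mean(np.square(errs))) < 0.15


class TestBendingAngle:
    @staticmethod
    def fiber_scene(angle_deg, width=6, shape=(200, 260)):
        img = np.full(shape, 255.0)
        img[170:, :] = 0.0  # bath
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        slope = math.tan(math.radians(angle_deg))
        center = 60 + slope * cc  # rows grow downward
        img[np.abs(rr - center) <= width / 2] = 0.0
        return make_frame(ndimage.gaussian_filter(img, 1.0))

    def test_straight_fiber_30_degrees(self):
        frame = self.fiber_scene(30.0)
        alpha = measure_bending_angle(frame, (20, 140))
        assert math.degrees(alpha) == pytest.approx(30.0, abs=0.2)

    def test_parallel_fiber_zero(self):
        frame = self.fiber_scene(0.0)
        alpha = measure_bending_angle(frame, (20, 140))
        assert math.degrees(alpha) == pytest.approx(0.0, abs=0.2)

    def test_bent_beam_matches_oracle_end_slope(self):
        from capadh.synthetic import beam_oracle

        E, length, d = 3.0e9, 1e-2, 70e-6
        I = math.pi * d**4 / 64
        F = math.radians(8.0) * 2 * E * I / length**2
        sol = beam_oracle(E, length, d, F)
        # render the last 15% of the beam near the contact point
        scale = 20e-6
        img = np.full((300, 300), 255.0)
        img[280:, :] = 0.0
        sel = sol.s > 0.85 * length
        cols = (sol.x[sel] - sol.x[sel][0]) / scale + 20
        rows = 100 + (sol.y[sel] - sol.y[sel][0]) / scale
        rr, cc = np.mgrid[:300, :300]
        center = np.interp(cc, cols, rows, left=np.nan, right=np.nan)
        img[np.abs(rr - center) <= 4] = 0.0
        frame = make_frame(ndimage.gaussian_filter(img, 1.0),
                           scale=scale)
        alpha = measure_bending_angle(frame, (25, 90))
        assert math.degrees(alpha) == pytest.approx(math.degrees(sol.alpha),
                                                    abs=0.5)


class TestEquivariance:
    def test_translation_and_rescaling(self):
        truth = SyntheticTruth(seed=13, camera=CameraModel(noise_sigma=0.0))
        frames, _, _ = render_frames(truth, 3)
        fr = frames[1]
        loc = locate_meniscus(extract_silhouette(fr))
        # horizontal translation by 10 px moves every x by 10 * scale
        rolled = make_frame(np.roll(fr.image, 10, axis=1),
                            scale=fr.pixel_scale)
        loc2 = locate_meniscus(extract_silhouette(rolled))
        assert loc2.axis_x - loc.axis_x == pytest.approx(
            10 * fr.pixel_scale, abs=0.2 * fr.pixel_scale
        )
        # pixel-scale rescaling scales all physical outputs
        half = make_frame(fr.image, scale=fr.pixel_scale / 2)
        loc3 = locate_meniscus(extract_silhouette(half))
        assert loc3.r_tip == pytest.approx(loc.r_tip / 2, rel=1e-9)
        assert loc3.baseline_y == pytest.approx(loc.baseline_y / 2, rel=1e-9)


class TestSequenceIO:
    def test_write_load_round_trip(self, tmp_path):
        truth = SyntheticTruth(seed=2)
        frames, _, _ = render_frames(truth, 3)
        out = write_sequence(frames, tmp_path / "seq")
        loaded, meta = load_sequence(out)
        assert len(loaded) == len(frames)
        assert loaded[0].pixel_scale == frames[0].pixel_scale
        assert np.array_equal(loaded[2].image, frames[2].image)
        assert loaded[1].stage_position == pytest.approx(
            frames[1].stage_position
        )

    def test_missing_sidecar(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(DataError):
            load_sequence(tmp_path / "empty")

    def test_manual_points_dialect(self, tmp_path):
        csv_path = tmp_path / "points.csv"
        csv_path.write_text(
            "frame_index,x_px,y_px,label\n"
            "0,10.5,20.25,flank\n0,12,18,flank\n0,50,5,tip\n"
            "1,0,40,baseline\n"
        )
        pts = read_manual_points(csv_path)
        assert set(pts) == {0, 1}
        assert pts[0]["flank"].shape == (2, 2)
        assert pts[0]["tip"][0, 1] == 5.0
        bad = tmp_path / "bad.csv"
        bad.write_text("frame_index,x_px,y_px,label\n0,1,2,nonsense\n")
        with pytest.raises(DataError):
            read_manual_points(bad)
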