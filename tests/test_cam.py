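"""GradCAM++ arithmetic against brute-force oracles, upsampling, Demons
registration, cohort averaging and highlighting."""

import dataclasses

import numpy as np
import pytest

from pelvistrat.cam import (
    CamTensors,
    average_heatmap,
    capture_layer,
    case_heatmap,
    demons_register,
    dice,
    export_heatmap,
    gradcampp_alpha,
    gradcampp_heatmap,
    pick_reference,
    top_fraction_highlight,
    upsample_heatmap,
    warp_with_field,
)
from pelvistrat.errors import ConfigurationError
from pelvistrat.model import DifficultyNet, desk_config
from pelvistrat.phantom import PhantomSpec, generate_pelvis_phantom


def alpha_oracle(f, g):
    """Independent per-channel, per-voxel triple loop for the alpha weights."""
    C = f.shape[0]
    alpha = np.zeros_like(f, dtype=np.float64)
    for c in range(C):
        s = 0.0
        for idx in np.ndindex(f.shape[1:]):
            s += float(f[c][idx]) * float(g[c][idx]) ** 3
        for idx in np.ndindex(f.shape[1:]):
            denom = 2.0 * float(g[c][idx]) ** 2 + s
            if denom == 0.0:
                denom = 1.0
            alpha[c][idx] = float(g[c][idx]) ** 2 / denom
    return alpha


def heatmap_oracle(f, g, alpha):
    C = f.shape[0]
    heat = np.zeros(f.shape[1:], dtype=np.float64)
    for c in range(C):
        w = 0.0
        for idx in np.ndindex(f.shape[1:]):
            w += alpha[c][idx] * max(float(g[c][idx]), 0.0)
        heat += w * f[c].astype(np.float64)
    return np.maximum(heat, 0.0)


class TestAlpha:
    def test_zero_gradient_gives_zero_alpha(self, rng):
        t = CamTensors(f=rng.random((2, 3, 3, 3)).astype(np.float32), g=np.zeros((2, 3, 3, 3), dtype=np.float32))
        np.testing.assert_array_equal(gradcampp_alpha(t), 0.0)

    def test_single_unit_voxel_gives_one_third(self):
        f = np.zeros((1, 2, 2, 2), dtype=np.float32)
        g = np.zeros((1, 2, 2, 2), dtype=np.float32)
        f[0, 0, 0, 0] = 1.0
        g[0, 0, 0, 0] = 1.0
        alpha = gradcampp_alpha(CamTensors(f=f, g=g))
        assert alpha[0, 0, 0, 0] == pytest.approx(1 / 3)
        assert alpha[0, 1, 1, 1] == 0.0  # zero gradient -> zero weight

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            f = rng.standard_normal((3, 2, 3, 2)).astype(np.float32)
            g = rng.standard_normal((3, 2, 3, 2)).astype(np.float32)
            t = CamTensors(f=f, g=g)
            np.testing.assert_allclose(gradcampp_alpha(t), alpha_oracle(f, g), atol=1e-9)

    def test_nonfinite_inputs_rejected(self):
        f = np.full((1, 2, 2, 2), np.nan, dtype=np.float32)
        with pytest.raises(ValueError):
            gradcampp_alpha(CamTensors(f=f, g=np.zeros_like(f)))


class TestHeatmap:
    def test_nonpositive_gradients_give_zero_heatmap(self, rng):
        f = rng.random((2, 3, 3, 3)).astype(np.float32)
        g = -rng.random((2, 3, 3, 3)).astype(np.float32)
        t = CamTensors(f=f, g=g)
        np.testing.assert_array_equal(gradcampp_heatmap(t, gradcampp_alpha(t)), 0.0)

    def test_uniform_single_channel_heatmap_value(self):
        f = np.ones((1, 2, 2, 2), dtype=np.float32)
        g = np.full((1, 2, 2, 2), 0.5, dtype=np.float32)
        t = CamTensors(f=f, g=g)
        alpha = gradcampp_alpha(t)
        w = float(np.sum(alpha * np.maximum(g, 0)))
        np.testing.assert_allclose(gradcampp_heatmap(t, alpha), w)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            f = rng.standard_normal((4, 3, 3, 3)).astype(np.float32)
            g = rng.standard_normal((4, 3, 3, 3)).astype(np.float32)
            t = CamTensors(f=f, g=g)
            alpha = gradcampp_alpha(t)
            np.testing.assert_allclose(gradcampp_heatmap(t, alpha), heatmap_oracle(f, g, alpha), atol=1e-9)


class TestCapture:
    def test_feature_map_matches_forward_and_gradient_nonzero(self, rng):
        net = DifficultyNet(desk_config(), seed=0).eval()
        vol = rng.integers(0, 2, (32, 32, 32)).astype(np.float32)
        clin = np.full(3, 0.5, dtype=np.float32)
        tensors, score = capture_layer(net, "layer4", vol, clin)
        assert tensors.f.shape == tensors.g.shape
        assert 0 < score < 1
        res = net.forward(vol[None], clin[None])
        np.testing.assert_allclose(tensors.f, res.stages["layer4"].data[0], atol=1e-6)
        assert np.abs(tensors.g).max() > 0

    def test_unknown_layer_tag_rejected(self, rng):
        net = DifficultyNet(desk_config(), seed=0)
        with pytest.raises(ConfigurationError):
            capture_layer(net, "layer9", np.zeros((32, 32, 32), np.float32), np.full(3, 0.5))


class TestUpsample:
    def test_equal_shapes_identity(self, rng):
        h = rng.random((8, 8, 8))
        np.testing.assert_array_equal(upsample_heatmap(h, (8, 8, 8)), h)

    def test_constant_stays_constant(self):
        h = np.full((4, 4, 4), 2.5)
        np.testing.assert_allclose(upsample_heatmap(h, (16, 16, 16)), 2.5)

    def test_smooth_mass_approximately_preserved(self):
        x, y, z = np.mgrid[:8, :8, :8]
        h = np.exp(-(((x - 3.5) ** 2 + (y - 3.5) ** 2 + (z - 3.5) ** 2) / 8)).astype(float)
        up = upsample_heatmap(h, (32, 32, 32))
        mass_in = h.sum()  # voxel volume 1 on coarse grid
        mass_out = up.sum() / 64  # 4^3 fine voxels per coarse voxel
        assert mass_out == pytest.approx(mass_in, rel=0.05)


class TestDemons:
    def phantom(self, seed, width=20.0):
        spec = dataclasses.replace(PhantomSpec(), inlet_width_mm=width, jitter_mm=0.8)
        return generate_pelvis_phantom(spec, seed)[0]

    def test_self_registration_displacement_negligible(self):
        vol = self.phantom(0)
        field, warped = demons_register(vol, vol, spacing=1.5)
        assert np.abs(field).mean() < 0.1
        np.testing.assert_array_equal(warped, vol)

    def test_known_translation_recovered(self):
        vol = self.phantom(1)
        moved = np.roll(vol, 3, axis=0)
        field, warped = demons_register(moved, vol, spacing=1.5)
        fg = vol > 0
        # displacement along x inside the foreground should approach +3 voxels
        assert abs(field[..., 0][fg].mean() - 3.0) < 1.0
        assert dice(warped, vol) > dice(moved, vol)

    def test_overlap_never_degrades_on_phantom_pair(self):
        a = self.phantom(2, width=18.0)
        b = self.phantom(3, width=24.0)
        _, warped = demons_register(a, b, spacing=1.5)
        assert dice(warped, b) >= dice(a, b)


class TestAveraging:
    def test_single_case_returns_itself(self, rng):
        vol = rng.integers(0, 2, (8, 8, 8)).astype(np.uint8)
        heat = rng.random((8, 8, 8))
        skel, mean_heat = average_heatmap([vol], [heat])
        np.testing.assert_allclose(skel, vol)
        np.testing.assert_allclose(mean_heat, heat)

    def test_identical_cases_average_to_individual(self):
        vol = generate_pelvis_phantom(PhantomSpec(), 5)[0]
        heat = np.zeros(vol.shape)
        heat[16, 16, 16] = 2.0
        skel, mean_heat = average_heatmap([vol, vol, vol], [heat, heat, heat], spacing=1.5)
        np.testing.assert_allclose(skel, vol, atol=1e-6)
        np.testing.assert_allclose(mean_heat, heat, atol=1e-3)

    def test_aligned_hotspots_average_to_half(self):
        """Hotspot present in one of two identical cases -> mean value halves."""
        vol = generate_pelvis_phantom(PhantomSpec(), 6)[0]
        hot = np.zeros(vol.shape)
        hot[16, 16, 16] = 2.0
        _, mean_heat = average_heatmap([vol, vol], [hot, np.zeros(vol.shape)], reference_index=0, spacing=1.5)
        assert mean_heat[16, 16, 16] == pytest.approx(1.0, abs=1e-3)

    def test_reference_is_median_foreground_case(self):
        vols = [np.zeros((4, 4, 4)), np.ones((4, 4, 4)), np.pad(np.ones((2, 2, 2)), 1)]
        assert pick_reference(vols) == 2  # counts 0, 64, 8 -> median 8


class TestHighlight:
    def test_full_count_marks_everything(self, rng):
        h = rng.random((6, 6, 6))
        assert top_fraction_highlight(h, count=h.size).all()

    def test_half_percent_of_large_grid_is_64000_voxels(self):
        h = np.zeros(12_800_000, dtype=np.float32).reshape(400, 200, 160)
        mask = top_fraction_highlight(h, fraction=0.005)
        assert int(mask.sum()) == 64_000

    def test_strictly_decreasing_heat_selects_prefix(self):
        h = np.arange(27, 0, -1, dtype=float).reshape(3, 3, 3)
        mask = top_fraction_highlight(h, count=5)
        assert mask.reshape(-1)[:5].all() and not mask.reshape(-1)[5:].any()

    def test_tie_break_is_lexicographic(self):
        h = np.ones(10)
        mask = top_fraction_highlight(h.reshape(10, 1, 1), count=4)
        assert mask.reshape(-1)[:4].all() and not mask.reshape(-1)[4:].any()


class TestExport:
    def test_nifti_round_trip_and_snapshots(self, tmp_path, rng):
        from pelvistrat.preprocess import read_volume

        heat = rng.random((8, 8, 8)).astype(np.float32)
        paths = export_heatmap(heat, tmp_path / "heat", spacing=1.5)
        back = read_volume(paths[0])
        np.testing.assert_allclose(back.values, heat, atol=1e-7)
        assert len(paths) == 4 and all(p.exists() for p in paths)

    def test_endpoint_colors_span_jet(self, tmp_path):
        import matplotlib

        heat = np.zeros((4, 4, 4), dtype=np.float32)
        heat[0, 0, 0] = 1.0
        export_heatmap(heat, tmp_path / "h", spacing=1.0)
        from PIL import Image

        img = np.asarray(Image.open(tmp_path / "h_sagittal.png"))
        cmap = matplotlib.colormaps["jet"]
        lo = np.array(cmap(0.0)[:3]) * 255
        assert np.abs(img[1, 1].astype(float) - lo).max() <= 1  # cold voxel -> first JET color


def test_case_heatmap_is_nonnegative_and_input_shaped(rng):
    net = DifficultyNet(desk_config(), seed=1).eval()
    vol = generate_pelvis_phantom(PhantomSpec(), 7)[0].astype(np.float32)
    heat = case_heatmap(net, vol, np.full(3, 0.5), layer_tag="layer3")
    assert heat.shape == vol.shape
    assert heat.min() >= 0


def test_warp_with_identity_field_is_identity(rng):
    vol = rng.random((8, 8, 8)).astype(np.float32)
    field = np.zeros((8, 8, 8, 3), dtype=np.float32)
    out = warp_with_field(vol, field, spacing=1.0)
    np.testing.assert_allclose(out, vol, atol=1e-5)
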