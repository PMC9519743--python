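"""Slice-wise volume correction, depth encoding and mosaic stitching."""

import numpy as np
import pytest

from biraster.core import AScanVolume
from biraster.preprocess import map_project
from biraster.volume3d import correct_volume, depth_encode, stitch_segments


@pytest.fixture()
def toy_volume(rng):
    return AScanVolume(rng.random((6, 16, 16)).astype(np.float32), (10.0, 4.4, 4.0))


class TestCorrectVolume:
    def test_identity_calibrated_network_preserves_volume(self, identity_generator):
        gen, pairs, split = identity_generator
        planes = np.stack([pairs[i].target_img for i in split.test[:8]])
        vol = AScanVolume(planes.transpose(0, 2, 1), (10.0, 4.4, 4.0))
        out = correct_volume(vol, gen)
        mad = float(np.abs(out.amplitudes - vol.amplitudes).mean())
        assert mad < 0.02

    def test_shape_and_metadata_conserved(self, identity_generator, toy_volume):
        gen, _, _ = identity_generator
        out = correct_volume(toy_volume, gen)
        assert out.shape == toy_volume.shape
        assert out.spacing_um == toy_volume.spacing_um

    def test_planes_processed_independently(self, identity_generator, toy_volume):
        gen, _, _ = identity_generator
        perm = np.array([3, 1, 5, 0, 2, 4])
        direct = correct_volume(toy_volume, gen).amplitudes
        permuted = correct_volume(
            AScanVolume(toy_volume.amplitudes[perm], toy_volume.spacing_um), gen
        ).amplitudes
        inv = np.argsort(perm)
        np.testing.assert_allclose(permuted[inv], direct, atol=1e-6)


class TestDepthEncode:
    def test_single_bright_plane_gives_uniform_hue(self):
        amp = np.full((5, 8, 8), 0.1, np.float32)
        amp[3] = 0.9
        enc = depth_encode(AScanVolume(amp, (10, 1, 1)))
        assert np.all(enc.depth_of_max == 3)

    def test_extreme_depths_map_to_colormap_endpoints(self):
        import matplotlib

        amp = np.full((4, 2, 1), 0.1, np.float32)
        amp[0, 0, 0] = 1.0  # maximum at shallowest depth for x=0
        amp[3, 1, 0] = 1.0  # maximum at deepest depth for x=1
        enc = depth_encode(AScanVolume(amp, (10, 1, 1)), colormap="viridis")
        cmap = matplotlib.colormaps["viridis"]
        np.testing.assert_allclose(enc.rgb[0, 0], np.array(cmap(0.0)[:3]), atol=1e-6)
        np.testing.assert_allclose(enc.rgb[0, 1], np.array(cmap(1.0)[:3]), atol=1e-6)

    def test_depth_of_max_matches_argmax_oracle(self, rng):
        amp = rng.random((5, 6, 7)).astype(np.float32)
        enc = depth_encode(AScanVolume(amp, (10, 1, 1)))
        for x in range(6):
            for y in range(7):
                assert enc.depth_of_max[y, x] == int(np.argmax(amp[:, x, y]))

    def test_brightness_equals_normalized_map(self, toy_volume):
        """rgb = colormap(hue) * (MAP / max): the brightness channel is the MAP."""
        import matplotlib

        enc = depth_encode(toy_volume)
        mapimg = map_project(toy_volume)
        brightness = mapimg / mapimg.max()
        nz = toy_volume.shape[0]
        hue = matplotlib.colormaps[enc.colormap](enc.depth_of_max / (nz - 1))[..., :3]
        np.testing.assert_allclose(enc.rgb, hue * brightness[..., None], atol=1e-6)


class TestStitchSegments:
    def test_single_segment_identity(self, rng):
        img = rng.random((8, 10))
        np.testing.assert_allclose(stitch_segments([(img, (0, 0))]), img)

    def test_equal_constant_overlap_blends_to_constant(self):
        seg = np.full((8, 8), 0.6)
        out = stitch_segments([(seg, (0, 0)), (seg, (0, 4))])
        np.testing.assert_allclose(out, 0.6)

    def test_disjoint_segments_copied_exactly(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4))
        out = stitch_segments([(a, (0, 0)), (b, (0, 4))])
        np.testing.assert_allclose(out[:, :4], a)
        np.testing.assert_allclose(out[:, 4:], b)

    def test_uncovered_pixels_warn_and_zero_fill(self, rng):
        with pytest.warns(UserWarning, match="not covered"):
            out = stitch_segments([(rng.random((4, 4)), (0, 0)), (rng.random((4, 4)), (8, 8))])
        assert out[0, 8] == 0.0
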