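"""Channel formation: soft thresholding, partial reconstructions, channel
stacks and their contracts."""

import numpy as np
import pytest

from xletseg.formations import (
    COMBO_ORDER,
    ChannelStack,
    DenoiseSpec,
    build_combo,
    build_formation,
    build_simple,
    build_two_channel,
    estimate_threshold,
    highpass_image,
    lowpass_image,
    normalize_channel,
    soft_threshold,
)
from xletseg.image import Image2D
from xletseg.transforms import TRANSFORMS, default_spec, forward


# ---------------------------------------------------------------------------
# soft thresholding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "x,lam,expected",
    [(5.0, 2.0, 3.0), (-1.0, 2.0, 0.0), (-5.0, 2.0, -3.0), (0.0, 1.0, 0.0)],
)
def test_soft_threshold_closed_form(x, lam, expected):
    assert soft_threshold(np.array([x]), lam)[0] == pytest.approx(expected)


def test_soft_threshold_zero_lambda_is_identity(rng):
    band = rng.normal(size=(16, 16))
    assert np.array_equal(soft_threshold(band, 0.0), band)


def test_soft_threshold_negative_lambda_rejected():
    with pytest.raises(ValueError):
        soft_threshold(np.ones(4), -1.0)


def test_soft_threshold_complex_preserves_phase():
    z = np.array([3 + 4j, 0.5 + 0.5j])  # magnitudes 5 and ~0.707
    out = soft_threshold(z, 2.0)
    assert abs(out[0]) == pytest.approx(3.0)
    assert np.angle(out[0]) == pytest.approx(np.angle(z[0]))
    assert out[1] == 0.0


def test_universal_threshold_properties(rng):
    assert estimate_threshold(np.zeros((8, 8))) == 0.0
    band = np.random.default_rng(11).normal(0.0, 1.0, 4096)
    ref = np.sqrt(2.0 * np.log(4096))
    assert 0.9 * ref <= estimate_threshold(band) <= 1.1 * ref
    b2 = rng.normal(size=(32, 32))
    assert estimate_threshold(3.0 * b2) == pytest.approx(3.0 * estimate_threshold(b2))


def test_universal_threshold_removes_noise_energy():
    """On pure Gaussian noise the universal threshold kills >= 95% of the
    band energy (Monte-Carlo over seeded bands)."""
    kept = []
    for seed in range(100):
        band = np.random.default_rng(seed).normal(0.0, 1.0, (64, 64))
        out = soft_threshold(band, estimate_threshold(band))
        kept.append(np.sum(out**2) / np.sum(band**2))
    assert max(kept) <= 0.05


# ---------------------------------------------------------------------------
# partial reconstructions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", TRANSFORMS)
def test_lowpass_plus_highpass_equals_input(name, rng):
    """lp + hp partial reconstructions sum to the original (denoise off)."""
    for _ in range(5):
        img = Image2D(rng.random((64, 64)))
        pyr = forward(img, default_spec(name, 64))
        total = lowpass_image(pyr) + highpass_image(pyr)
        assert np.max(np.abs(total - img.pixels)) <= 1e-6


def test_constant_image_partial_reconstructions(constant_image64):
    pyr = forward(constant_image64, default_spec("contourlet", 64))
    assert np.max(np.abs(lowpass_image(pyr) - 0.43)) <= 1e-8
    assert np.max(np.abs(highpass_image(pyr))) <= 1e-8


def test_highpass_peaks_at_edges():
    """An intensity strip produces maximal edge response within 2 px of its
    boundaries, for every transform."""
    x = np.zeros((64, 64))
    x[:, 24:40] = 0.8
    img = Image2D(x)
    edge_cols = np.array([23, 24, 39, 40])
    for name in TRANSFORMS:
        hp = np.abs(highpass_image(forward(img, default_spec(name, 64))))
        args = np.argmax(hp, axis=1)
        dist = np.min(np.abs(args[:, None] - edge_cols[None, :]), axis=1)
        assert dist.max() <= 2


def test_denoising_reduces_pure_noise_energy(rng):
    noise_img = Image2D(np.clip(0.5 + rng.normal(0, 0.1, (64, 64)), 0, 1))
    for name in TRANSFORMS:
        pyr = forward(noise_img, default_spec(name, 64))
        e_off = np.sum(highpass_image(pyr) ** 2)
        e_on = np.sum(highpass_image(pyr, DenoiseSpec(enabled=True)) ** 2)
        assert e_on < e_off


def test_denoising_is_elementwise_monotone(rng):
    """Soft thresholding never increases any detail coefficient magnitude."""
    img = Image2D(rng.random((64, 64)))
    for name in TRANSFORMS:
        pyr = forward(img, default_spec(name, 64))
        den = pyr.map_bands(lambda b: soft_threshold(b, estimate_threshold(b)))
        for lvl, lvl_d in zip(pyr.levels, den.levels):
            for b, d in zip(lvl, lvl_d):
                assert np.all(np.abs(d) <= np.abs(b) + 1e-12)


# ---------------------------------------------------------------------------
# normalization and stacks
# ---------------------------------------------------------------------------

def test_normalize_channel_cases():
    assert np.array_equal(normalize_channel(np.full((4, 4), 3.0)), np.zeros((4, 4)))
    ramp = np.linspace(0, 1, 16).reshape(4, 4)
    assert np.allclose(normalize_channel(ramp), ramp)
    arr = np.array([[-3.0, 5.0], [1.0, 1.0]])
    out = normalize_channel(arr)
    assert out.min() == 0.0 and out.max() == 1.0


def test_two_channel_contract(phantom_pair):
    img, _ = phantom_pair
    for name in TRANSFORMS:
        stack = build_two_channel(img, name)
        assert stack.channels.shape == (64, 64, 2)
        assert stack.channel_labels == (f"{name}_lp", f"{name}_hp")
        assert stack.channels.min() >= 0.0 and stack.channels.max() <= 1.0


def test_two_channel_constant_input_zero_edge_channel(constant_image64):
    stack = build_two_channel(constant_image64, "dtcwt")
    assert np.all(stack.channels[:, :, 1] == 0.0)


def test_edge_channel_brighter_on_cyst_boundary(phantom_pair):
    """Mean edge response over cyst-boundary pixels exceeds the interior."""
    from scipy.ndimage import binary_dilation, binary_erosion

    img, mask = phantom_pair
    b = mask.astype(bool)
    boundary = binary_dilation(b, iterations=2) & ~binary_erosion(b, iterations=2)
    interior = binary_erosion(b, iterations=3)
    assert interior.any()
    for name in TRANSFORMS:
        hp = build_two_channel(img, name).channels[:, :, 1]
        assert hp[boundary].mean() > hp[interior].mean()


def test_combo_channel_contracts(phantom_pair):
    img, _ = phantom_pair
    c4 = build_combo(img, "combo4")
    assert c4.n_channels == 4
    assert all(lbl.endswith("_lp") for lbl in c4.channel_labels)
    assert tuple(l.split("_")[0] for l in c4.channel_labels) == COMBO_ORDER
    c5 = build_combo(img, "combo5")
    assert c5.n_channels == 5
    assert c5.channel_labels[4] == "contourlet_hp"
    c5hh = build_combo(img, "combo5hh")
    assert c5hh.n_channels == 5
    assert all(lbl.endswith("_hp") for lbl in c5hh.channel_labels[:4])
    assert c5hh.channel_labels[4] == "contourlet_lp"
    with pytest.raises(ValueError):
        build_combo(img, "combo6")


def test_combo5hh_constant_input_is_all_zero(constant_image64):
    stack = build_combo(constant_image64, "combo5hh")
    assert np.all(stack.channels == 0.0)


def test_shared_channels_bitwise_identical_across_paths(phantom_pair):
    """combo5's contourlet edge channel equals the two-channel build
    bit-for-bit under the same spec."""
    img, _ = phantom_pair
    c5 = build_combo(img, "combo5")
    tc = build_two_channel(img, "contourlet")
    assert np.array_equal(c5.channels[:, :, 4], tc.channels[:, :, 1])
    assert np.array_equal(c5.channels[:, :, 1], tc.channels[:, :, 0])


def test_formation_determinism(phantom_pair):
    img, _ = phantom_pair
    a = build_formation(img, "combo5hh")
    b = build_formation(img, "combo5hh")
    assert np.array_equal(a.channels, b.channels)


def test_simple_formation_and_stack_validation(phantom_pair):
    img, _ = phantom_pair
    s = build_simple(img)
    assert s.channels.shape == (64, 64, 1)
    assert np.array_equal(s.channels[:, :, 0], img.pixels)
    with pytest.raises(ValueError):  # wrong channel count for the formation
        ChannelStack(np.zeros((8, 8, 3)), "combo4", ("a", "b", "c"))
    with pytest.raises(ValueError):  # duplicate labels
        ChannelStack(np.zeros((8, 8, 2)), "two_ch", ("a", "a"))
    with pytest.raises(ValueError):
        build_formation(img, "nonesuch")


def test_denoise_spec_validation():
    with pytest.raises(ValueError):
        DenoiseSpec(enabled=True, threshold_rule="fixed")  # missing lambda
    with pytest.raises(ValueError):
        DenoiseSpec(threshold_rule="magic")
    DenoiseSpec(enabled=True, threshold_rule="fixed", fixed_lambda=0.1)
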