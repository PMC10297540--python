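"""Transform correctness: perfect reconstruction, linearity, band geometry,
energy conservation, shift invariance and serialization."""

import numpy as np
import pytest

from xletseg.image import DimensionError, Image2D
from xletseg.transforms import (
    TRANSFORMS,
    ConfigurationError,
    InversionError,
    TransformSpec,
    coefficient_energy,
    default_spec,
    forward,
    inverse,
    load_pyramid,
    save_pyramid,
)

SPECS = {
    "contourlet": TransformSpec("contourlet", levels=2, directions_per_level=(4, 8)),
    "dtcwt": TransformSpec("dtcwt", levels=3),
    "curvelet": TransformSpec("curvelet", levels=3),
    "circlet": TransformSpec("circlet", n_rings=5),
}
ROUNDTRIP_TOL = {"contourlet": 1e-8, "dtcwt": 1e-8, "curvelet": 1e-6, "circlet": 1e-8}


@pytest.mark.parametrize("name", TRANSFORMS)
def test_roundtrip_identity(name, rng):
    """forward -> inverse recovers the input to float round-off."""
    for _ in range(5):
        img = Image2D(rng.random((64, 64)))
        rec = inverse(forward(img, SPECS[name]))
        assert np.max(np.abs(rec.pixels - img.pixels)) <= ROUNDTRIP_TOL[name]


@pytest.mark.parametrize("name", TRANSFORMS)
def test_zero_image_gives_zero_bands(name):
    pyr = forward(Image2D(np.zeros((64, 64))), SPECS[name])
    assert np.all(pyr.lowpass == 0)
    for lvl in pyr.levels:
        for band in lvl:
            assert np.all(np.abs(band) == 0)


@pytest.mark.parametrize("name", TRANSFORMS)
def test_linearity_on_convex_combinations(name, rng):
    """forward(a*x + b*y) = a*forward(x) + b*forward(y), band-wise."""
    x, y = rng.random((64, 64)), rng.random((64, 64))
    a, b = 0.3, 0.7
    p_mix = forward(Image2D(a * x + b * y), SPECS[name])
    px, py = forward(Image2D(x), SPECS[name]), forward(Image2D(y), SPECS[name])
    assert np.max(np.abs(p_mix.lowpass - (a * px.lowpass + b * py.lowpass))) < 1e-10
    for lm, lx, ly in zip(p_mix.levels, px.levels, py.levels):
        for bm, bx, by in zip(lm, lx, ly):
            assert np.max(np.abs(bm - (a * bx + b * by))) < 1e-10


def test_band_counts_and_shapes():
    img = Image2D(np.random.default_rng(3).random((64, 64)))
    pyr = forward(img, SPECS["dtcwt"])
    assert pyr.band_counts() == [6, 6, 6]
    assert all(np.iscomplexobj(b) for lvl in pyr.levels for b in lvl)
    pyr = forward(img, SPECS["contourlet"])
    assert pyr.band_counts() == [4, 8]
    assert pyr.lowpass.shape == (16, 16)  # decimated by 2^levels
    pyr = forward(img, SPECS["circlet"])
    assert pyr.band_counts() == [4]  # n_rings - 1 ring bands + low-pass


def test_input_validation_errors():
    rng = np.random.default_rng(0)
    with pytest.raises(DimensionError):
        forward(Image2D(rng.random((48, 48))), SPECS["contourlet"])
    with pytest.raises(ConfigurationError):  # too many levels for the size
        forward(
            Image2D(rng.random((16, 16))),
            TransformSpec("contourlet", levels=4, directions_per_level=(4, 4, 4, 4)),
        )
    with pytest.raises(ConfigurationError):  # non-power-of-two directions
        TransformSpec("contourlet", levels=1, directions_per_level=(3,))
    from xletseg.transforms import contourlet_forward

    with pytest.raises(ConfigurationError):  # spec/transform mismatch
        contourlet_forward(Image2D(rng.random((64, 64))), TransformSpec("dtcwt"))


def test_curvelet_tight_frame_energy(rng):
    """Total coefficient energy equals image energy (Parseval)."""
    for _ in range(5):
        img = Image2D(rng.random((64, 64)))
        pyr = forward(img, SPECS["curvelet"])
        ratio = coefficient_energy(pyr) / np.sum(img.pixels**2)
        assert abs(ratio - 1.0) < 1e-6


def test_dtcwt_shift_invariance_of_band_energy(rng):
    """A 1-px shift changes per-band energies by at most 5% relative."""
    x = rng.random((64, 64))
    p1 = forward(Image2D(x), SPECS["dtcwt"])
    p2 = forward(Image2D(np.roll(x, 1, axis=1)), SPECS["dtcwt"])
    for l1, l2 in zip(p1.levels, p2.levels):
        e1 = np.array([np.sum(np.abs(b) ** 2) for b in l1])
        e2 = np.array([np.sum(np.abs(b) ** 2) for b in l2])
        assert np.max(np.abs(e1 - e2) / e1) <= 0.05


def test_circlet_partition_of_unity_and_ring_localization():
    """Bands sum to the image; an on-grid radial sinusoid lands >= 90% of
    its energy in the ring whose centre matches its frequency."""
    rng = np.random.default_rng(4)
    img = Image2D(rng.random((64, 64)))
    pyr = forward(img, SPECS["circlet"])
    total = pyr.lowpass + sum(np.asarray(b) for b in pyr.levels[0])
    assert np.max(np.abs(total - img.pixels)) <= 1e-8

    # ring 2 of 5 rings is centred at radius pi/2 = grid frequency 16/64
    s = 0.5 + 0.5 * np.cos(2 * np.pi * 16 * np.arange(64) / 64)
    pyr = forward(Image2D(np.tile(s, (64, 1))), SPECS["circlet"])
    ring_energy = [np.sum(np.asarray(b) ** 2) for b in pyr.levels[0]]
    ac_total = sum(ring_energy)  # DC sits in the low-pass
    assert ring_energy[1] / ac_total >= 0.9


def test_contourlet_impulse_excites_all_directions():
    impulse = np.zeros((64, 64))
    impulse[32, 32] = 1.0
    pyr = forward(
        Image2D(impulse), TransformSpec("contourlet", levels=1, directions_per_level=(4,))
    )
    energies = [np.sum(b**2) for b in pyr.levels[0]]
    assert len(energies) == 4
    assert all(e > 1e-6 for e in energies)


def test_constant_image_lives_in_lowpass(constant_image64):
    pyr = forward(constant_image64, SPECS["contourlet"])
    rec = inverse(pyr.zero_details())
    assert np.max(np.abs(rec.pixels - 0.43)) <= 1e-8
    assert max(np.max(np.abs(b)) for lvl in pyr.levels for b in lvl) <= 1e-8


def test_zeroed_details_never_gain_energy(rng):
    """Low-pass-only reconstruction has no more energy than the input."""
    from xletseg.transforms import inverse_array

    for name in TRANSFORMS:
        img = Image2D(rng.random((64, 64)))
        low = inverse_array(forward(img, SPECS[name]).zero_details())
        assert np.sum(low**2) <= np.sum(img.pixels**2) * (1 + 1e-9)


@pytest.mark.parametrize("name", TRANSFORMS)
def test_serialization_roundtrip(tmp_path, name, rng):
    img = Image2D(rng.random((64, 64)))
    pyr = forward(img, SPECS[name])
    path = tmp_path / f"{name}.xlt"
    save_pyramid(path, pyr)
    back = load_pyramid(path)
    assert back.transform == name
    assert np.array_equal(back.lowpass, pyr.lowpass)
    for la, lb in zip(back.levels, pyr.levels):
        for ba, bb in zip(la, lb):
            assert np.array_equal(ba, bb)
    rec = inverse(back)
    assert np.max(np.abs(rec.pixels - img.pixels)) <= ROUNDTRIP_TOL[name]


def test_tampered_geometry_raises(rng):
    pyr = forward(Image2D(rng.random((64, 64))), SPECS["contourlet"])
    pyr.geometry.pop("side")
    with pytest.raises(InversionError):
        inverse(pyr)
    pyr2 = forward(Image2D(rng.random((64, 64))), SPECS["curvelet"])
    pyr2.geometry["levels"] = 7
    with pytest.raises(InversionError):
        inverse(pyr2)
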