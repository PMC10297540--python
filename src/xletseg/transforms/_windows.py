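"""Frequency-plane window construction shared by the FFT-based transforms.

All windows are built from the Meyer-style smooth step ``nu`` with the
complementarity property ``nu(t) + nu(1 - t) = 1``.  Two partition flavours
are provided:

* *amplitude* partitions (windows sum to one) — used by the circlet rings,
  the contourlet directional filter bank and the complex oriented wavelet
  frame, whose inverses are additive;
* *energy* partitions (squared windows sum to one) — used by the curvelet
  tight frame, where Parseval equality is required.

Radial coordinates use the sup-norm ``max(|wx|, |wy|)`` for the dyadic
(square-annulus) decompositions, which makes the low-pass support an exact
sub-grid so it can be decimated by spectral cropping without loss, and the
Euclidean norm for the circlet rings.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def nu(t: np.ndarray) -> np.ndarray:
    """Polynomial smooth step: 0 for t<=0, 1 for t>=1, C^3 in between."""
    t = np.clip(t, 0.0, 1.0)
    return t**4 * (35.0 - 84.0 * t + 70.0 * t**2 - 20.0 * t**3)


@lru_cache(maxsize=64)
def freq_grid(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (wx, wy, r_inf, theta) on the n x n FFT grid, in radians.

    ``wy`` varies along axis 0 (rows), ``wx`` along axis 1 (columns);
    ``theta = atan2(wy, wx)`` in (-pi, pi].
    """
    w = 2.0 * np.pi * np.fft.fftfreq(n)
    wy = w[:, None] * np.ones((1, n))
    wx = np.ones((n, 1)) * w[None, :]
    r_inf = np.maximum(np.abs(wx), np.abs(wy))
    theta = np.arctan2(wy, wx)
    for a in (wx, wy, r_inf, theta):
        a.setflags(write=False)
    return wx, wy, r_inf, theta


def _radial_pair(r: np.ndarray, cutoff: float, energy: bool) -> tuple[np.ndarray, np.ndarray]:
    """High/low window pair with transition over [cutoff, 2*cutoff]."""
    s = nu(r / cutoff - 1.0)
    if energy:
        hi = np.sin(0.5 * np.pi * s)
        lo = np.cos(0.5 * np.pi * s)
    else:
        hi = s
        lo = 1.0 - s
    return hi, lo


def dyadic_radial_windows(
    n: int, levels: int, energy: bool
) -> tuple[list[np.ndarray], np.ndarray]:
    """Square-annulus band-pass windows ``D_1..D_J`` (fine -> coarse) and the
    residual low-pass ``L``.

    Amplitude mode: ``L + sum(D_j) = 1`` exactly.
    Energy mode: ``L^2 + sum(D_j^2) = 1`` exactly.
    The low-pass support lies strictly inside ``|w|_inf < pi * 2^(1-J)``, so
    it can be represented on an ``n / 2^(J-1)`` grid.
    """
    _, _, r, _ = freq_grid(n)
    details: list[np.ndarray] = []
    carry = np.ones_like(r)
    for j in range(1, levels + 1):
        hi, lo = _radial_pair(r, np.pi * 2.0 ** (-j), energy)
        details.append(carry * hi)
        carry = carry * lo
    return details, carry


def _bump(u: np.ndarray, energy: bool) -> np.ndarray:
    """Unit-translate partition bump supported on (-1, 1)."""
    w = np.where(u < 0.0, nu(1.0 + u), nu(1.0 - u))
    w[np.abs(u) >= 1.0] = 0.0
    if energy:
        w = np.sin(0.5 * np.pi * w)
    return w


def _negate_grid(arr: np.ndarray) -> np.ndarray:
    """Value at the negated FFT-grid frequency: a[(-i) % n, (-j) % n]."""
    return np.roll(arr[::-1, ::-1], 1, axis=(0, 1))


def angular_windows(n: int, n_dir: int, energy: bool) -> list[np.ndarray]:
    """``n_dir`` orientation windows on the half-turn (theta mod pi).

    Window k is centred at ``(k + 0.5) * pi / n_dir`` and overlaps only its
    two neighbours; together they form an exact (amplitude or energy)
    partition of unity over orientation.  Windows are symmetrized under
    FFT-grid frequency negation (the sampled Nyquist rows break the
    analytic theta-mod-pi symmetry), so bands of real images stay real.
    """
    _, _, _, theta = freq_grid(n)
    phi = np.mod(theta, np.pi)  # orientation in [0, pi)
    delta = np.pi / n_dir
    out = []
    for k in range(n_dir):
        center = (k + 0.5) * delta
        # wrap the offset into [-pi/2, pi/2) half-turns of the orientation circle
        u = (phi - center + np.pi / 2.0) % np.pi - np.pi / 2.0
        w = _bump(u / delta, energy)
        if energy:  # symmetrize squares to keep the energy partition exact
            w = np.sqrt(0.5 * (w**2 + _negate_grid(w**2)))
        else:
            w = 0.5 * (w + _negate_grid(w))
        out.append(w)
    if n_dir == 1:
        return [np.ones_like(phi)]
    return out


def halfplane_factor(n: int) -> np.ndarray:
    """Indicator of the ``wy > 0`` half-plane with self-conjugate rows
    (``wy`` equal to 0 or Nyquist) weighted 1/2, so that
    ``hp(w) + hp(-w) = 1`` for every sampled frequency."""
    _, wy, _, _ = freq_grid(n)
    hp = np.where(wy > 0.0, 1.0, 0.0)
    self_conj = (wy == 0.0) | np.isclose(np.abs(wy), np.pi)
    hp[self_conj] = 0.5
    return hp


def ring_windows(n: int, n_rings: int) -> list[np.ndarray]:
    """``n_rings`` concentric raised-cosine-style radial windows (Euclidean
    radius) forming an amplitude partition of unity; ring 0 is the low-pass,
    the outermost ring extends to the spectrum corners."""
    if n_rings < 2:
        raise ValueError("n_rings must be >= 2")
    wx, wy, _, _ = freq_grid(n)
    r = np.hypot(wx, wy)
    delta = np.pi / (n_rings - 1)
    u = r / delta
    out = []
    for k in range(n_rings):
        w = _bump(u - k, energy=False)
        if k == n_rings - 1:
            w = np.where(u >= k, 1.0, w)  # cover the corners beyond pi
        out.append(w)
    return out


def crop_indices(n: int, m: int) -> np.ndarray:
    """FFT-grid index vector selecting the centred ``m``-subgrid of an
    ``n``-grid (frequencies ``-m/2 .. m/2 - 1``)."""
    if m > n or m < 1:
        raise ValueError("invalid crop size")
    return np.concatenate([np.arange(0, m // 2 + m % 2), np.arange(n - m // 2, n)])


def spectral_crop(spectrum: np.ndarray, m: int) -> np.ndarray:
    idx = crop_indices(spectrum.shape[0], m)
    return spectrum[np.ix_(idx, idx)]


def spectral_embed(small: np.ndarray, n: int) -> np.ndarray:
    m = small.shape[0]
    idx = crop_indices(n, m)
    out = np.zeros((n, n), dtype=small.dtype)
    out[np.ix_(idx, idx)] = small
    return out
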