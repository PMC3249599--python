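"""Frequency-domain texture families: Fourier power spectrum bands, a Gabor
filter bank, and log-Gabor phase congruency.

All three operate on the full 2-D FFT of the patch, so filtering is
circular-convolution; the DC bin is always removed (or zeroed in the
filters), which makes every feature invariant to a constant gray offset.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .registry import (
    FOURIER_N_RINGS,
    FOURIER_N_WEDGES,
    GABOR_FREQUENCIES,
    GABOR_ORIENTATIONS,
)

_EPS = 1e-12

# ---------------------------------------------------------------------------
# Fourier power spectrum bands
# ---------------------------------------------------------------------------


def fourier_features(patch: np.ndarray) -> np.ndarray:
    """Fractional power in 8 radial rings and 6 angular wedges.

    The windowless power spectrum has its DC term removed; rings are
    equal-width in radius (cycles per image, width ``side/2 / 8``, the last
    ring absorbing the spectrum corners) and wedges fold the half-plane
    symmetry into 6 bins of 30 degrees.  Each feature is band power divided
    by total non-DC power, so rings sum to 1 and wedges sum to 1 whenever
    the patch is not constant; a zero-power patch yields all zeros.
    """
    g = np.asarray(patch, dtype=np.float64)
    side = g.shape[0]
    F = np.fft.fft2(g)
    P = np.abs(F) ** 2
    P[0, 0] = 0.0
    total = P.sum()
    if total <= _EPS:
        return np.zeros(FOURIER_N_RINGS + FOURIER_N_WEDGES)

    fy = np.fft.fftfreq(side)[:, None] * side  # cycles / image
    fx = np.fft.fftfreq(side)[None, :] * side
    r = np.hypot(fy, fx)
    ring_width = (side / 2.0) / FOURIER_N_RINGS
    edges = ring_width * np.arange(1, FOURIER_N_RINGS)
    ring_idx = np.digitize(r, edges)
    rings = np.bincount(
        ring_idx.ravel(), weights=P.ravel(), minlength=FOURIER_N_RINGS
    )[:FOURIER_N_RINGS]

    ang = np.degrees(np.arctan2(fy, fx)) % 180.0
    wedge_idx = np.minimum(
        (ang / (180.0 / FOURIER_N_WEDGES)).astype(np.int64), FOURIER_N_WEDGES - 1
    )
    wedges = np.bincount(
        wedge_idx.ravel(), weights=P.ravel(), minlength=FOURIER_N_WEDGES
    )[:FOURIER_N_WEDGES]

    return np.concatenate([rings, wedges]) / total


# ---------------------------------------------------------------------------
# Gabor bank
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _gabor_bank(side: int) -> tuple:
    """Frequency-domain Gabor filters (Gaussian envelopes around each wave
    vector, ~1 octave bandwidth, DC zeroed), cached per patch side."""
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    bank = []
    for f0 in GABOR_FREQUENCIES:
        # half-amplitude points one octave apart: sigma_f = f0 / (3 sqrt(2 ln 2))
        sigma = f0 / (3.0 * np.sqrt(2.0 * np.log(2.0)))
        for theta in GABOR_ORIENTATIONS:
            t = np.radians(theta)
            u0 = f0 * np.cos(t)
            v0 = f0 * np.sin(t)
            H = np.exp(-((fx - u0) ** 2 + (fy - v0) ** 2) / (2.0 * sigma**2))
            H[0, 0] = 0.0
            bank.append(H)
    return tuple(bank)


def gabor_features(patch: np.ndarray) -> np.ndarray:
    """Mean and standard deviation of the response magnitude of a 24-filter
    Gabor bank (4 center frequencies x 6 orientations, 1 octave bandwidth).

    Filters are analytic (one-sided in the frequency plane), so the response
    magnitude is the local amplitude envelope.  A filter with orientation
    ``theta`` is tuned to gratings whose wave vector points ``theta`` degrees
    from the column axis (rows growing downward).
    """
    g = np.asarray(patch, dtype=np.float64)
    F = np.fft.fft2(g)
    out = np.empty(2 * len(GABOR_FREQUENCIES) * len(GABOR_ORIENTATIONS))
    for i, H in enumerate(_gabor_bank(g.shape[0])):
        mag = np.abs(np.fft.ifft2(F * H))
        out[2 * i] = mag.mean()
        out[2 * i + 1] = mag.std()
    return out


# ---------------------------------------------------------------------------
# Phase congruency
# ---------------------------------------------------------------------------

PC_NSCALE = 4
PC_NORIENT = 6
PC_MIN_WAVELENGTH = 3.0
PC_MULT = 2.0
PC_SIGMA_ONF = 0.55
PC_NOISE_K = 2.0
PC_DTHETA_ON_SIGMA = 1.3


@lru_cache(maxsize=8)
def _log_gabor_bank(side: int) -> tuple:
    """Log-Gabor radial filters x angular spreads, cached per patch side."""
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    radius = np.hypot(fy, fx)
    radius[0, 0] = 1.0  # avoid log(0); DC is zeroed below
    theta = np.arctan2(-fy, fx)  # y up for angular bookkeeping
    sintheta = np.sin(theta)
    costheta = np.cos(theta)

    radial = []
    log_sigma = np.log(PC_SIGMA_ONF)
    for s in range(PC_NSCALE):
        wavelength = PC_MIN_WAVELENGTH * PC_MULT**s
        f0 = 1.0 / wavelength
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * log_sigma**2))
        lg[0, 0] = 0.0
        radial.append(lg)

    spreads = []
    theta_sigma = (np.pi / PC_NORIENT) / PC_DTHETA_ON_SIGMA
    for o in range(PC_NORIENT):
        angle = o * np.pi / PC_NORIENT
        ds = sintheta * np.cos(angle) - costheta * np.sin(angle)
        dc = costheta * np.cos(angle) + sintheta * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spreads.append(np.exp(-(dtheta**2) / (2.0 * theta_sigma**2)))

    return tuple(radial), tuple(spreads)


def phase_congruency_map(patch: np.ndarray) -> np.ndarray:
    """Phase congruency map in [0, 1] via a log-Gabor quadrature bank.

    Follows the standard energy-over-amplitude construction with a noise
    threshold estimated from the finest-scale amplitude (compensation
    constant ``k = 2``).  A constant patch maps to an all-zero PC map.
    """
    g = np.asarray(patch, dtype=np.float64)
    side = g.shape[0]
    F = np.fft.fft2(g - g.mean())
    radial, spreads = _log_gabor_bank(side)

    if np.abs(F).sum() <= _EPS:
        return np.zeros_like(g)

    total_energy = np.zeros_like(g)
    total_ampl = np.zeros_like(g)
    for spread in spreads:
        e_list = []
        o_list = []
        sum_e = np.zeros_like(g)
        sum_o = np.zeros_like(g)
        sum_an = np.zeros_like(g)
        tau = 0.0
        for s, lg in enumerate(radial):
            resp = np.fft.ifft2(F * lg * spread)
            e, od = resp.real, resp.imag
            an = np.abs(resp)
            e_list.append(e)
            o_list.append(od)
            sum_e += e
            sum_o += od
            sum_an += an
            if s == 0:
                tau = np.median(an) / np.sqrt(np.log(4.0))
        x_energy = np.sqrt(sum_e**2 + sum_o**2) + _EPS
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy
        energy = np.zeros_like(g)
        for e, od in zip(e_list, o_list):
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)
        # expected noise response accumulated over scales
        tau_total = tau * (1.0 - (1.0 / PC_MULT) ** PC_NSCALE) / (1.0 - 1.0 / PC_MULT)
        noise_mean = tau_total * np.sqrt(np.pi / 2.0)
        noise_sigma = tau_total * np.sqrt((4.0 - np.pi) / 2.0)
        T = noise_mean + PC_NOISE_K * noise_sigma
        total_energy += np.maximum(energy - T, 0.0)
        total_ampl += sum_an
    pc = total_energy / (total_ampl + _EPS)
    return np.clip(pc, 0.0, 1.0)


def phasecong_features(patch: np.ndarray) -> np.ndarray:
    """Moments of the phase congruency map plus edge density (PC > 0.5)."""
    pc = phase_congruency_map(patch).ravel()
    mean = float(pc.mean())
    std = float(pc.std())
    if std > _EPS:
        skew = float(np.mean((pc - mean) ** 3) / std**3)
        kurt = float(np.mean((pc - mean) ** 4) / std**4)
    else:
        skew = 0.0
        kurt = 0.0
    density = float(np.mean(pc > 0.5))
    return np.array([mean, std, skew, kurt, density])
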