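"""Signal extraction: stepping-curve fits and transmission/dark-field images.

Each pixel's intensity series over the scan phases is fit with the sinusoid
``a0 + a1 cos(phi_k + phi)`` by linear least squares (for equally spaced
phases this coincides with the discrete-Fourier estimate).  Transmission and
dark-field images follow as ratios against the sample-free reference scan:

    T = a0_sample / a0_reference
    D = (a1_sample / a0_sample) / (a1_reference / a0_reference)

Both images come from the same exposure and are therefore pixel-registered by
construction; retrieval never resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interferometer import SteppingScan

#: retrieved dark-field values are clipped here before analysis; photon noise
#: can push the visibility ratio above 1 in non-scattering regions
D_CLIP = (0.0, 1.5)


@dataclass
class RadiographPair:
    """Registered transmission and dark-field images from one exposure."""

    transmission: np.ndarray
    darkfield: np.ndarray
    phase: np.ndarray  # differential fringe phase, computed but not analyzed
    gap_mask: np.ndarray  # True where retrieval is undefined / tile gaps
    artifact_mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return tuple(self.transmission.shape)


def fit_stepping_curve(series: np.ndarray, phases: np.ndarray):
    """Least-squares sinusoid fit of per-pixel stepping curves.

    Parameters
    ----------
    series : array, shape (n_steps, ...)
        Intensity samples; the step axis is the first axis.
    phases : array, shape (n_steps,)
        Known scan phases in radians, strictly increasing.

    Returns
    -------
    (a0, a1, phi)
        Mean, non-negative modulation amplitude, and phase of
        ``a0 + a1 cos(phi_k + phi)``; ``phi`` is 0 where the modulation
        vanishes.
    """
    series = np.asarray(series, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if series.shape[0] != phases.shape[0]:
        raise ValueError("series and phases disagree on the number of steps")
    if series.shape[0] < 3:
        raise ValueError("need at least 3 phase samples per pixel")
    if np.any(np.diff(phases) <= 0):
        raise ValueError("phases must be strictly increasing")

    # model: a0 + c cos(phi_k) + s sin(phi_k), with a1 cos(phi_k + phi)
    # = a1 cos(phi) cos(phi_k) - a1 sin(phi) sin(phi_k)
    A = np.stack([np.ones_like(phases), np.cos(phases), np.sin(phases)], axis=1)
    P = np.linalg.pinv(A)  # (3, n_steps)
    flat = series.reshape(series.shape[0], -1)
    coef = P @ flat
    a0 = coef[0].reshape(series.shape[1:])
    c = coef[1]
    s = coef[2]
    a1 = np.hypot(c, s).reshape(series.shape[1:])
    phi = np.arctan2(-s, c).reshape(series.shape[1:])
    # below numerical noise the phase is undefined; report 0 by convention
    phi = np.where(a1 > 1e-12 * np.maximum(np.abs(a0), 1.0), phi, 0.0)
    return a0, a1, phi


def retrieve(sample: SteppingScan, reference: SteppingScan) -> RadiographPair:
    """Retrieve the transmission/dark-field pair from a sample/reference scan.

    Pixels where the reference mean or modulation (or the sample mean)
    vanishes are flagged in the gap mask and set to NaN; scan-level tile-gap
    masks are propagated.  The dark-field image is clipped to ``D_CLIP``.
    """
    if sample.grid_shape != reference.grid_shape:
        raise ValueError("sample and reference grids differ")
    if sample.phases.shape != reference.phases.shape or not np.allclose(
        sample.phases, reference.phases
    ):
        raise ValueError("sample and reference phase grids differ")

    a0s, a1s, phis = fit_stepping_curve(sample.frames, sample.phases)
    a0r, a1r, phir = fit_stepping_curve(reference.frames, reference.phases)

    eps = 1e-12
    bad = (a0r <= eps) | (a1r <= eps * np.maximum(a0r, 1.0)) | (a0s <= eps)
    for scan in (sample, reference):
        if scan.gap_mask is not None:
            bad |= scan.gap_mask

    with np.errstate(divide="ignore", invalid="ignore"):
        T = a0s / a0r
        D = (a1s / a0s) / (a1r / a0r)
        phase = np.angle(np.exp(1j * (phis - phir)))
    T = np.where(bad, np.nan, T)
    D = np.where(bad, np.nan, np.clip(D, *D_CLIP))
    phase = np.where(bad, np.nan, phase)

    prov = {
        "sample": dict(sample.provenance),
        "reference": dict(reference.provenance),
        "sample_seed": sample.settings.rng_seed,
        "n_steps": int(sample.settings.n_steps),
        "v0": sample.geometry.v0,
    }
    return RadiographPair(
        transmission=T, darkfield=D, phase=phase, gap_mask=bad, provenance=prov
    )
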