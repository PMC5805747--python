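"""Fringe-scanning acquisition forward model for the grating interferometer.

The scanner is a three-grating arrangement (source grating G0, reference
grating G1, analyzer G2) in which an intensity fringe pattern is scanned over
every detector pixel.  The per-pixel intensity over the scan phases follows a
stepping curve

    I_k = I0 * T * (1 + v0 * D * cos(phi_k + phi_pixel)),

with ``T = exp(-attenuation)`` the transmission, ``D = exp(-scatter)`` the
dark-field visibility reduction, ``v0`` the reference visibility and
``phi_pixel`` the flat-field fringe phase, oriented in horizontal lines
(fringes orthogonal to the vertical scan direction).  The model is effective
and monochromatic: spectral/beam-hardening physics and wave propagation are
out of scope; the line integrals of the phantom translate directly into T
and D.  Photon noise is Poisson per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import SeedSequence, default_rng

from .calibration import get_calibration
from .phantom import FOV_CM, ThoraxPhantom


@dataclass(frozen=True)
class ScannerGeometry:
    """Grating periods, distances and detector grid of the prototype scanner."""

    p0_um: float = 68.72  # G0 period
    p1_um: float = 8.73  # G1 period
    p2_um: float = 10.0  # G2 period
    duty0: float = 0.7
    duty1: float = 0.5
    duty2: float = 0.5
    source_detector_m: float = 2.0
    d_g0g1_m: float = 1.60
    d_g1g2_m: float = 0.25
    sample_offset_upstream_g1_m: float = 0.056
    true_pixel_um: float = 444.0
    effective_pixel_um: float = 360.0
    fov_object_cm: tuple[float, float] = FOV_CM
    v0: float = 0.25  # reference fringe visibility

    def __post_init__(self):
        for name in (
            "p0_um", "p1_um", "p2_um", "source_detector_m", "d_g0g1_m",
            "d_g1g2_m", "true_pixel_um", "effective_pixel_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.v0 < 1.0:
            raise ValueError("v0 must lie in (0, 1)")
        if self.effective_pixel_um >= self.true_pixel_um:
            raise ValueError("effective pixel must be smaller than true pixel")

    @property
    def grid_shape(self) -> tuple[int, int]:
        px_cm = self.effective_pixel_um * 1e-4
        return (
            int(round(self.fov_object_cm[0] / px_cm)),
            int(round(self.fov_object_cm[1] / px_cm)),
        )

    @classmethod
    def from_calibration(cls, name: str = "paper2018", scale: str = "full",
                         **overrides) -> "ScannerGeometry":
        from .phantom import SCALES

        cal = get_calibration(name)
        eff_um = SCALES[scale] * 1e4
        # reduced scales emulate coarser binning: keep the true/effective ratio
        params = dict(
            v0=cal["v0"],
            effective_pixel_um=eff_um,
            true_pixel_um=444.0 / 360.0 * eff_um,
        )
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class AcquisitionSettings:
    """Sampling and noise settings of one fringe scan."""

    n_steps: int = 8
    photons_per_step: float | None = 2500.0  # None -> noiseless expectation
    fringe_period_rows: float = 16.0
    motion_amplitude: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_steps < 3:
            raise ValueError(
                "n_steps must be >= 3 (mean, modulation and phase per pixel)"
            )
        if self.photons_per_step is not None and self.photons_per_step <= 0:
            raise ValueError("photons_per_step must be > 0")

    @classmethod
    def from_calibration(cls, name: str = "paper2018", **overrides
                         ) -> "AcquisitionSettings":
        cal = get_calibration(name)
        params = dict(
            n_steps=int(cal["n_steps"]),
            photons_per_step=cal["photons_per_step"],
            fringe_period_rows=cal["fringe_period_rows"],
            motion_amplitude=cal["motion_amplitude"],
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class SteppingScan:
    """Per-pixel intensity series over the fringe-scan phases."""

    frames: np.ndarray  # (n_steps, rows, cols) photon counts / intensities
    phases: np.ndarray  # (n_steps,) radians in [0, 2pi), strictly increasing
    geometry: ScannerGeometry
    settings: AcquisitionSettings
    is_reference: bool = False
    gap_mask: np.ndarray | None = None  # True where grating tile gaps
    provenance: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return tuple(self.frames.shape[1:])

    def copy(self) -> "SteppingScan":
        return SteppingScan(
            frames=self.frames.copy(),
            phases=self.phases.copy(),
            geometry=self.geometry,
            settings=self.settings,
            is_reference=self.is_reference,
            gap_mask=None if self.gap_mask is None else self.gap_mask.copy(),
            provenance=dict(self.provenance),
        )


def step_phases(n_steps: int) -> np.ndarray:
    """Equally spaced scan phases over one fringe period."""
    return 2.0 * np.pi * np.arange(n_steps) / n_steps


def fringe_phase_map(grid_shape: tuple[int, int], period_rows: float) -> np.ndarray:
    """Flat-field fringe phase: horizontal lines, varying along rows."""
    rows = np.arange(grid_shape[0], dtype=float)
    phi_row = 2.0 * np.pi * rows / period_rows
    return np.broadcast_to(phi_row[:, None], grid_shape)


def _expectation(
    geometry: ScannerGeometry,
    settings: AcquisitionSettings,
    grid_shape: tuple[int, int],
    T: np.ndarray | float = 1.0,
    D: np.ndarray | float = 1.0,
) -> np.ndarray:
    i0 = settings.photons_per_step if settings.photons_per_step else 1.0
    phases = step_phases(settings.n_steps)
    phi_pix = fringe_phase_map(grid_shape, settings.fringe_period_rows)
    # cos(phi_k + phi_pixel) varies only along rows -> build (n, R) then bcast
    cosmat = np.cos(phases[:, None] + phi_pix[:, 0][None, :])  # (n, R)
    expect = i0 * T * (1.0 + geometry.v0 * D * cosmat[:, :, None])
    full = (settings.n_steps,) + tuple(grid_shape)
    if expect.shape != full:  # scalar T/D: broadcast columns explicitly
        expect = np.ascontiguousarray(np.broadcast_to(expect, full))
    return expect


def _finalize(expect, geometry, settings, is_reference, extra=None):
    if settings.photons_per_step is not None:
        rng = default_rng(SeedSequence([settings.rng_seed & 0x7FFFFFFF,
                                        1 if is_reference else 2]))
        frames = rng.poisson(np.clip(expect, 0.0, None)).astype(np.float64)
    else:
        frames = expect
    scan = SteppingScan(
        frames=frames,
        phases=step_phases(settings.n_steps),
        geometry=geometry,
        settings=settings,
        is_reference=is_reference,
        provenance=dict(extra or {}),
    )
    return scan


def simulate_reference(
    geometry: ScannerGeometry,
    settings: AcquisitionSettings,
    grid_shape: tuple[int, int] | None = None,
    noiseless: bool = False,
) -> SteppingScan:
    """Simulate a sample-free (flat-field) fringe scan.

    The reference is noiseless when ``noiseless`` is set or
    ``settings.photons_per_step`` is None; the default analysis pipeline
    uses a noiseless reference (well-averaged flat field).
    """
    grid = grid_shape or geometry.grid_shape
    eff = settings if not noiseless else replace(settings, photons_per_step=None)
    expect = _expectation(geometry, eff, grid)
    if eff.photons_per_step is None and settings.photons_per_step is not None:
        # keep intensities on the photon scale even for the noiseless path
        expect = expect * settings.photons_per_step
    return _finalize(expect, geometry, eff, is_reference=True)


def simulate_scan(
    phantom: ThoraxPhantom,
    geometry: ScannerGeometry,
    settings: AcquisitionSettings,
) -> SteppingScan:
    """Simulate the fringe scan of a phantom.

    Per pixel the expectation is ``I0 T (1 + v0 D cos(phi_k + phi_pixel))``
    with the same flat-field fringe phase as the paired reference.
    """
    grid = phantom.grid_shape
    geo_grid = geometry.grid_shape
    if grid != geo_grid:
        raise ValueError(
            f"phantom grid {grid} does not match geometry grid {geo_grid}"
        )
    T = np.exp(-phantom.attenuation_map)[None, :, :]
    D = np.exp(-phantom.scatter_map)[None, :, :]
    expect = _expectation(geometry, settings, grid, T=T, D=D)
    return _finalize(
        expect, geometry, settings, is_reference=False,
        extra={"phantom_state": phantom.state, "phantom_seed": phantom.meta.get("rng_seed")},
    )


def add_motion_artifact(
    scan: SteppingScan,
    edge_mask: np.ndarray,
    amplitude: float,
    column_sigma_px: float = 40.0,
    ex_vivo: bool = False,
) -> SteppingScan:
    """Add a step-correlated cardiac-motion perturbation along an edge mask.

    Organs entering/exiting a region while the fringe pattern is scanned over
    it modulate the stepping curve coherently; signal extraction then
    misreads the modulation, producing horizontal streaks (orthogonal to the
    scan direction) at the heart edge in the retrieved dark-field image.
    Only rows intersecting ``edge_mask`` are perturbed, with a Gaussian
    falloff away from the masked columns.  ``amplitude`` is relative to the
    local mean intensity; 0 is the identity.
    """
    if ex_vivo and amplitude > 0:
        import warnings

        warnings.warn(
            "motion artifact requested on an ex-vivo scan; applying anyway",
            stacklevel=2,
        )
    if amplitude == 0:
        return scan
    if edge_mask.shape != scan.grid_shape:
        raise ValueError("edge mask shape does not match the scan grid")
    out = scan.copy()
    R, C = scan.grid_shape
    rows_hit = edge_mask.any(axis=1)
    if not rows_hit.any():
        return out
    # per-row column weight: Gaussian falloff from the masked columns
    cols = np.arange(C, dtype=float)
    weight = np.zeros((R, C))
    for r in np.flatnonzero(rows_hit):
        cc = np.flatnonzero(edge_mask[r])
        dist2 = (cols[None, :] - cc[:, None]) ** 2
        weight[r] = np.exp(-dist2.min(axis=0) / (2.0 * column_sigma_px**2))
    a0 = out.frames.mean(axis=0)
    psi = np.pi / 3.0  # fixed motion phase offset relative to the scan
    pert = np.cos(out.phases[:, None, None] + psi) * (amplitude * a0 * weight)[None]
    out.frames = out.frames + pert
    np.clip(out.frames, 0.0, None, out=out.frames)
    out.provenance["motion_amplitude"] = amplitude
    return out


def add_tile_gaps(scan: SteppingScan, gap_spec: list[dict]) -> SteppingScan:
    """Suppress fringe modulation inside grating tile-gap strips.

    ``gap_spec`` is a list of strips ``{"axis": "rows"|"cols",
    "start": int, "stop": int}``; within each strip the per-pixel deviation
    from the stepping-curve mean is shrunk to near zero, emulating the loss
    of visibility between grating half-tiles.  The strips are recorded in the
    scan's gap mask.
    """
    if not gap_spec:
        return scan
    out = scan.copy()
    R, C = out.grid_shape
    gap = np.zeros((R, C), dtype=bool) if out.gap_mask is None else out.gap_mask
    for strip in gap_spec:
        axis = strip.get("axis", "rows")
        s, e = int(strip["start"]), int(strip["stop"])
        if axis == "rows":
            gap[s:e, :] = True
        elif axis == "cols":
            gap[:, s:e] = True
        else:
            raise ValueError(f"unknown gap axis {axis!r}")
    mean = out.frames.mean(axis=0, keepdims=True)
    shrunk = mean + 0.02 * (out.frames - mean)
    out.frames = np.where(gap[None, :, :], shrunk, out.frames)
    out.gap_mask = gap
    out.provenance["tile_gaps"] = list(gap_spec)
    return out
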