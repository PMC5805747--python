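"""ROI statistics, the lung/pneumothorax CNR, and projected-area measurement.

The contrast-to-noise ratio between the lung and the air-filled pleural
cavity is

    CNR = |mu_L - mu_P| / sqrt(sigma_L^2 + sigma_P^2),

with plain means and sample standard deviations over the two regions of
interest.  Identical ROIs are applied to the transmission and dark-field
image of one exposure (they are registered by construction).  The measured
sigma mixes photon noise with "anatomical noise" - real signal variation
from unresolved tissue structure - which is exactly what limits
discriminability in practice.

Projected inflated-lung area behind the diaphragm is measured by
thresholding the (low-pass-filtered) dark-field image: strongly scattering
lung is directly and exclusively visible there, so pixels well below the
free-gas plateau are lung.  The pixel count times the squared object-plane
pixel size gives the area in cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .filtering import DEFAULT_FWHM_PX, DisplayImage, _as_quantitative, gaussian_lowpass
from .phantom import ThoraxPhantom


@dataclass
class ROI:
    """A pixel mask with a semantic label and placement provenance."""

    mask: np.ndarray
    label: str  # lung | pneumothorax | retro_lung_affected | retro_lung_control
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ROIStats:
    """Mean, sample standard deviation and size of one ROI."""

    mean: float
    sd: float
    n_pixels: int


def roi_stats(image, roi: ROI) -> ROIStats:
    """Plain mean and sample standard deviation over the ROI pixels."""
    img = _as_quantitative(image)
    if roi.mask.shape != img.shape:
        raise ValueError("ROI mask shape does not match the image")
    vals = img[roi.mask]
    if vals.size == 0:
        raise ValueError("empty ROI")
    if not np.all(np.isfinite(vals)):
        raise ValueError(
            f"ROI {roi.label!r} contains non-finite pixels (gap/artifact region?)"
        )
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return ROIStats(mean=float(vals.mean()), sd=sd, n_pixels=int(vals.size))


def cnr(image, roi_l: ROI, roi_p: ROI) -> float:
    """Contrast-to-noise ratio |mu_L - mu_P| / sqrt(sigma_L^2 + sigma_P^2)."""
    if (roi_l.mask & roi_p.mask).any():
        raise ValueError("lung and pneumothorax ROIs must be disjoint")
    sl = roi_stats(image, roi_l)
    sp = roi_stats(image, roi_p)
    denom = np.sqrt(sl.sd**2 + sp.sd**2)
    if denom == 0:
        raise ValueError("CNR undefined: both ROI standard deviations are zero")
    return float(abs(sl.mean - sp.mean) / denom)


# ---------------------------------------------------------------------------
# automatic ROI placement from phantom ground truth
# ---------------------------------------------------------------------------


def _erosion_px(pixel_size_cm: float, margin_cm: float) -> int:
    return max(1, int(round(margin_cm / pixel_size_cm)))


def auto_cnr_rois(
    phantom: ThoraxPhantom,
    side: str,
    roi_size_cm: float = 2.0,
    margin_cm: float = 0.11,
) -> tuple[ROI, ROI]:
    """Place the lung and pneumothorax ROIs for CNR analysis automatically.

    The pneumothorax ROI is the pleural gas band (eroded, restricted to
    chest rows); the lung ROI is a roughly ``roi_size_cm`` square of lung
    pixels adjacent to the band, excluding ribs and eroded away from every
    boundary - mirroring the manual placement rule of excluding the rib cage
    and mediastinal structures.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    px = phantom.pixel_size
    er = _erosion_px(px, margin_cm)
    half = max(3, int(round(roi_size_cm / px / 2)))
    R, C = phantom.grid_shape
    mid = phantom.meta.get("mid_col", C // 2)
    cols = np.arange(C)[None, :]
    side_mask = cols < mid if side == "left" else cols >= mid
    d_row = phantom.meta.get("diaphragm_row", int(0.62 * R))
    chest_rows = np.arange(R)[:, None] < d_row

    gas = phantom.masks["pleural_gas"] & side_mask & chest_rows
    gas = gas & ~phantom.masks["ribs"]
    gas_er = ndimage.binary_erosion(gas, iterations=er) if gas.any() else gas
    if not gas_er.any():
        if not gas.any():
            raise ValueError(
                f"no lateral pleural gas on side {side!r}; cannot place the "
                "pneumothorax ROI (dorsal-only pneumothorax?)"
            )
        gas_er = gas  # very narrow band: fall back to the un-eroded mask

    rr, cc = np.nonzero(gas_er)
    rc = int(round(rr.mean()))
    row_lo, row_hi = max(0, rc - half), min(R, rc + half)
    gas_roi_mask = np.zeros((R, C), dtype=bool)
    gas_roi_mask[row_lo:row_hi] = gas_er[row_lo:row_hi]
    if gas_roi_mask.sum() < 50:
        gas_roi_mask = gas_er  # keep enough pixels for a stable sd

    lung = phantom.masks[f"{side}_lung"] & ~phantom.masks["ribs"]
    lung = ndimage.binary_erosion(lung, iterations=er)
    # lung box adjacent (medial) to the gas band, vertically centred on it
    band_cols = np.nonzero(gas_roi_mask.any(axis=0))[0]
    inner = band_cols.max() + er if side == "left" else band_cols.min() - er
    if side == "left":
        col_lo, col_hi = inner, min(C, inner + 2 * half)
    else:
        col_lo, col_hi = max(0, inner - 2 * half), inner
    lung_roi_mask = np.zeros((R, C), dtype=bool)
    lung_roi_mask[row_lo:row_hi, col_lo:col_hi] = lung[row_lo:row_hi, col_lo:col_hi]
    if lung_roi_mask.sum() < 50:  # fall back to any eroded lung on that side
        lung_roi_mask = lung.copy()
        lung_roi_mask[~(chest_rows & side_mask)] = False

    prov = {"placement": "auto-from-truth-masks", "erosion_px": er, "side": side}
    return (
        ROI(lung_roi_mask, "lung", dict(prov)),
        ROI(gas_roi_mask, "pneumothorax", dict(prov)),
    )


def rois_from_json(spec: list[dict], grid_shape: tuple[int, int]) -> list[ROI]:
    """Build ROIs from a manual JSON description.

    Each entry: ``{"label": str, "runs": [[row, col_start, col_stop], ...]}``
    with 0-based, half-open column runs.
    """
    out = []
    for entry in spec:
        mask = np.zeros(grid_shape, dtype=bool)
        for row, c0, c1 in entry["runs"]:
            mask[int(row), int(c0): int(c1)] = True
        out.append(ROI(mask, entry["label"], {"placement": "manual-json"}))
    return out


# ---------------------------------------------------------------------------
# projected-area quantification
# ---------------------------------------------------------------------------


def retro_band_params(phantom: ThoraxPhantom, side: str) -> dict:
    """Analysis-band parameters for retro-diaphragmatic segmentation."""
    R, C = phantom.grid_shape
    r0, r1 = phantom.meta.get("retro_band_rows", (int(0.62 * R) + 1, int(0.97 * R)))
    return {
        "band_rows": (int(r0), int(r1)),
        "mid_col": int(phantom.meta.get("mid_col", C // 2)),
        "pixel_size_object": phantom.pixel_size,
    }


def segment_inflated_lung(
    darkfield,
    side: str,
    params: dict,
    threshold_factor: float = 0.70,
    plateau_floor: float = 0.80,
    fwhm_px: float = DEFAULT_FWHM_PX,
    closing_px: int = 2,
) -> np.ndarray:
    """Segment the scattering (inflated) retro-diaphragmatic lung on one side.

    The dark-field image is Gaussian low-pass filtered, restricted to the
    retro-diaphragmatic analysis band on the requested side, and thresholded
    at ``threshold_factor`` times the median of the free-gas/soft-tissue
    plateau (pixels with D above ``plateau_floor``); the result is
    morphologically closed, hole-filled, and reduced to its largest connected
    component.  Deterministic; returns an empty mask (with a warning) when no
    scattering component exists.
    """
    img = _as_quantitative(darkfield)
    if isinstance(darkfield, DisplayImage):  # pragma: no cover - guarded above
        raise ValueError("display-grade image rejected")
    smooth = gaussian_lowpass(np.nan_to_num(img, nan=1.0), fwhm_px)
    R, C = smooth.shape
    r0, r1 = params["band_rows"]
    mid = params["mid_col"]
    region = np.zeros((R, C), dtype=bool)
    if side == "left":
        region[r0:r1, :mid] = True
    elif side == "right":
        region[r0:r1, mid:] = True
    else:
        raise ValueError("side must be 'left' or 'right'")

    vals = smooth[region]
    plateau_vals = vals[vals >= plateau_floor]
    if plateau_vals.size < 10:
        plateau_vals = np.sort(vals)[vals.size // 2:]
    plateau = float(np.median(plateau_vals)) if plateau_vals.size else 1.0
    thr = threshold_factor * plateau

    mask = region & (smooth < thr)
    if not mask.any():
        import warnings

        warnings.warn(f"no inflated lung found on side {side!r}", stacklevel=2)
        return mask
    structure = ndimage.generate_binary_structure(2, 2)
    mask = ndimage.binary_closing(mask, structure=structure, iterations=closing_px)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def projected_area(mask: np.ndarray, pixel_size_object: float) -> float:
    """Projected area in the object plane: pixel count x pixel size squared."""
    if pixel_size_object <= 0:
        raise ValueError("pixel_size_object must be > 0")
    return float(np.count_nonzero(mask)) * pixel_size_object**2
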