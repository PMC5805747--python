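"""Synthetic porcine thorax projection phantoms with pneumothorax induction.

The phantom is a stylized 2-D posterior-anterior projection of a pig thorax in
abdominal position: an elliptical body, two lung fields separated by a
mediastinal (heart) band, curved rib bands, a diaphragm with an
attenuation gradient into the abdomen, and per-side retro-diaphragmatic lung
regions that project behind the diaphragm.  Two maps are produced:

``attenuation_map``
    dimensionless line integral; the ideal transmission is ``exp(-att)``.
``scatter_map``
    dimensionless dark-field line integral; the ideal visibility reduction
    (dark-field signal) is ``exp(-scatter)``.  Inflated lung scatters
    strongly; free pleural gas and soft tissue do not scatter at all.

Anatomical noise is modelled as two correlated Gaussian random fields: a
short-range granularity multiplying the lung scatter (unresolved alveolar
structure) and a long-range additive field on the attenuation map (overlying
soft-tissue structure).  Both are fixed per animal, i.e. they do not change
between the baseline and the pneumothorax exposure.

A pneumothorax is induced in one of two geometries:

* *lateral* — a pleural gas band is carved between the lateral rib cage and
  the lung, with width increasing monotonically in the instilled air volume;
* *dorsal* — air accumulating dorsally compresses the retro-diaphragmatic
  lung, shrinking its projected area by ``collapse_fraction``.

Because pleural air always rises to the uppermost (dorsal) space in abdominal
position, every pneumothorax also carries a dorsal collapse; the lateral band
is added on top of it for laterally visible pneumothoraces.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy import ndimage

from .calibration import get_calibration

# object-plane pixel size each scale maps to [cm]
SCALES = {"full": 0.036, "half": 0.072, "smoke": 0.144}
FOV_CM = (32.0, 35.0)  # rows x cols in the object plane
MIN_GRID = 128

REFERENCE_AP_DIAMETER = 20.2  # cm, cohort mean anterior-posterior diameter
REFERENCE_BODY_MASS = 25.8  # kg

MASK_LABELS = (
    "background",
    "left_lung",
    "right_lung",
    "pleural_gas",
    "retro_diaphragmatic_lung_left",
    "retro_diaphragmatic_lung_right",
    "ribs",
    "heart",
    "abdomen",
)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, contrast and texture parameters of one synthetic animal."""

    grid_shape: tuple[int, int] = (889, 972)
    pixel_size_object: float = 0.036  # cm
    ap_diameter: float = REFERENCE_AP_DIAMETER  # cm, scales tissue paths
    body_mass: float = REFERENCE_BODY_MASS  # kg, cosmetic only

    # anatomy layout (fractions of the grid)
    body_center: tuple[float, float] = (0.52, 0.50)
    body_semi: tuple[float, float] = (0.46, 0.44)
    lung_row_center: float = 0.38
    lung_row_semi: float = 0.23
    lung_col_centers: tuple[float, float] = (0.30, 0.70)  # left, right
    lung_col_semi: float = 0.14
    heart_center: tuple[float, float] = (0.46, 0.50)
    heart_semi: tuple[float, float] = (0.14, 0.10)
    diaphragm_frac: float = 0.62
    diaphragm_ramp_cm: float = 0.8
    n_ribs: int = 9
    rib_start_frac: float = 0.10
    rib_spacing_frac: float = 0.058
    rib_thickness_frac: float = 0.012
    rib_arc_frac: float = 0.03
    retro_area_cm2: tuple[float, float] = (57.6, 62.8)  # left, right
    retro_aspect: float = 0.75  # row semi-axis / col semi-axis
    max_gap_cm: float = 1.2  # lateral pleural gap at 500 ml

    # contrast (dimensionless line integrals)
    body_attenuation: float = 1.60
    lung_attenuation: float = 0.80
    gas_attenuation: float = 0.693
    rib_extra: float = 0.50
    heart_extra: float = 0.40
    abdomen_attenuation: float = 1.80
    retro_attn_extra: float = 0.20
    lung_scatter: float = 0.357
    retro_scatter: float = 0.60

    # texture
    lung_texture_rel: float = 0.34
    retro_texture_rel: float = 0.10
    lung_texture_corr_px: float = 6.0
    trans_texture_sd: float = 0.069
    trans_texture_corr_px: float = 30.0
    envelope_amp: float = 0.12

    rng_seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 2 or min(self.grid_shape) <= 0:
            raise ValueError("grid_shape must be two positive integers")
        if self.pixel_size_object <= 0:
            raise ValueError("pixel_size_object must be > 0")
        if self.lung_texture_corr_px < 1 or self.trans_texture_corr_px < 1:
            raise ValueError("texture correlation lengths must be >= 1 px")

    @classmethod
    def from_calibration(
        cls,
        name: str = "paper2018",
        scale: str = "full",
        rng_seed: int = 0,
        **overrides,
    ) -> "PhantomConfig":
        """Build a config from a named calibration at a named scale.

        Texture correlation lengths are stored in pixels at the native
        360 um grid and are rescaled here so the object-plane structure is
        scale-invariant.
        """
        cal = get_calibration(name)
        px = SCALES[scale]
        grid = (int(round(FOV_CM[0] / px)), int(round(FOV_CM[1] / px)))
        zoom = SCALES["full"] / px
        params = dict(
            grid_shape=grid,
            pixel_size_object=px,
            body_attenuation=cal["body_attenuation"],
            lung_attenuation=cal["lung_attenuation"],
            gas_attenuation=cal["gas_attenuation"],
            rib_extra=cal["rib_extra"],
            heart_extra=cal["heart_extra"],
            abdomen_attenuation=cal["abdomen_attenuation"],
            retro_attn_extra=cal["retro_attn_extra"],
            lung_scatter=cal["lung_scatter"],
            retro_scatter=cal["retro_scatter"],
            lung_texture_rel=cal["lung_texture_rel"],
            retro_texture_rel=cal["retro_texture_rel"],
            lung_texture_corr_px=max(1.0, cal["lung_texture_corr_px"] * zoom),
            trans_texture_sd=cal["trans_texture_sd"],
            trans_texture_corr_px=max(1.0, cal["trans_texture_corr_px"] * zoom),
            envelope_amp=cal["envelope_amp"],
            rng_seed=rng_seed,
        )
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class PneumothoraxSpec:
    """One induced unilateral pneumothorax.

    ``air_volume`` (ml) drives the lateral pleural gap width; the
    ``collapse_fraction`` is the fraction of retro-diaphragmatic projected
    lung area lost to dorsally accumulating air.  Both may be active for a
    lateral pneumothorax; a dorsal-only pneumothorax has no visible gap.
    """

    side: str  # "left" | "right" (image side, p.a. view)
    location: str = "lateral"  # "lateral" | "dorsal"
    air_volume: float = 0.0  # ml
    collapse_fraction: float = 0.0

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.location not in ("lateral", "dorsal"):
            raise ValueError(f"unknown location {self.location!r}")
        if not 0.0 <= self.air_volume <= 500.0:
            raise ValueError("air_volume must be within [0, 500] ml")
        if not 0.0 <= self.collapse_fraction < 1.0:
            raise ValueError("collapse_fraction must be within [0, 1)")


@dataclass
class ThoraxPhantom:
    """Projected line-integral maps plus ground truth for one animal/state."""

    attenuation_map: np.ndarray
    scatter_map: np.ndarray
    masks: dict[str, np.ndarray]
    truth: dict[str, float]
    state: str  # "baseline" | "pneumothorax"
    config: PhantomConfig
    meta: dict = field(default_factory=dict)

    @property
    def pixel_size(self) -> float:
        return self.config.pixel_size_object

    @property
    def grid_shape(self) -> tuple[int, int]:
        return tuple(self.attenuation_map.shape)

    def copy(self) -> "ThoraxPhantom":
        return ThoraxPhantom(
            attenuation_map=self.attenuation_map.copy(),
            scatter_map=self.scatter_map.copy(),
            masks={k: v.copy() for k, v in self.masks.items()},
            truth=dict(self.truth),
            state=self.state,
            config=self.config,
            meta=dict(self.meta),
        )


def gaussian_random_field(
    shape: tuple[int, int], corr_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian field with autocorrelation length ``corr_px``.

    White noise filtered with a Gaussian of sigma = corr/sqrt(2) has the
    autocovariance exp(-r^2 / (2 corr^2)); the realization is renormalized to
    unit sample variance so texture amplitudes are exact per animal.
    """
    noise = rng.standard_normal(shape)
    fld = ndimage.gaussian_filter(noise, sigma=corr_px / np.sqrt(2.0), mode="wrap")
    sd = fld.std()
    if sd == 0:  # pragma: no cover - degenerate 1x1 grids only
        return fld
    return (fld - fld.mean()) / sd


def _ellipse(rows, cols, cr, cc, ar, ac):
    return ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2


def _truth_from_masks(masks: dict[str, np.ndarray], px: float) -> dict[str, float]:
    area = px * px
    return {
        key: float(masks[key].sum()) * area
        for key in (
            "left_lung",
            "right_lung",
            "retro_diaphragmatic_lung_left",
            "retro_diaphragmatic_lung_right",
        )
    }


def generate_phantom(config: PhantomConfig) -> ThoraxPhantom:
    """Render a baseline (no pneumothorax) thorax phantom.

    Deterministic for a fixed ``config.rng_seed``.  Raises ``ValueError`` if
    the grid is too small to contain the anatomy (< 128 px per axis).
    """
    R, C = config.grid_shape
    if R < MIN_GRID or C < MIN_GRID:
        raise ValueError(
            f"grid {config.grid_shape} too small to contain the anatomy; "
            f"need at least {MIN_GRID} px per axis"
        )
    px = config.pixel_size_object
    rows = np.arange(R, dtype=float)[:, None]
    cols = np.arange(C, dtype=float)[None, :]
    rng = default_rng(SeedSequence(config.rng_seed))

    body = _ellipse(
        rows, cols, config.body_center[0] * R, config.body_center[1] * C,
        config.body_semi[0] * R, config.body_semi[1] * C,
    ) <= 1.0

    heart = (
        _ellipse(
            rows, cols, config.heart_center[0] * R, config.heart_center[1] * C,
            config.heart_semi[0] * R, config.heart_semi[1] * C,
        )
        <= 1.0
    ) & body

    d_row = int(round(config.diaphragm_frac * R))
    lung_rho = {}
    lungs = {}
    for side, cc_frac in zip(("left", "right"), config.lung_col_centers):
        rho2 = _ellipse(
            rows, cols, config.lung_row_center * R, cc_frac * C,
            config.lung_row_semi * R, config.lung_col_semi * C,
        )
        mask = (rho2 <= 1.0) & body & ~heart & (rows < d_row)
        lungs[side] = mask
        lung_rho[side] = rho2

    abdomen = body & (rows >= d_row)

    # retro-diaphragmatic lung: per-side ellipse sized to the target area
    retro = {}
    for side, target_cm2 in zip(("left", "right"), config.retro_area_cm2):
        n_px = target_cm2 / (px * px)
        ac = np.sqrt(n_px / (np.pi * config.retro_aspect))
        ar = config.retro_aspect * ac
        cr = d_row + ar + max(2.0, 0.005 * R)
        if cr + ar > 0.97 * R:
            raise ValueError(
                f"retro-diaphragmatic region ({target_cm2} cm^2) does not fit "
                f"below the diaphragm on a {config.grid_shape} grid"
            )
        cc = config.lung_col_centers[0 if side == "left" else 1] * C
        mask = (_ellipse(rows, cols, cr, cc, ar, ac) <= 1.0) & (rows > d_row)
        retro[side] = mask

    # curved rib bands across the thorax, attenuation-only
    ribs = np.zeros((R, C), dtype=bool)
    half_thick = max(1.0, config.rib_thickness_frac * R) / 2.0
    arc = config.rib_arc_frac * R * (((cols - 0.5 * C) / (0.5 * C)) ** 2)
    for i in range(config.n_ribs):
        center = (config.rib_start_frac + i * config.rib_spacing_frac) * R + arc
        ribs |= np.abs(rows - center) <= half_thick
    ribs &= body & (rows < d_row + 0.05 * R)

    ap_scale = config.ap_diameter / REFERENCE_AP_DIAMETER

    granularity = gaussian_random_field(
        (R, C), config.lung_texture_corr_px, rng
    )
    lowfreq = gaussian_random_field((R, C), config.trans_texture_corr_px, rng)

    att = np.zeros((R, C))
    att[body] = config.body_attenuation * ap_scale
    ramp_px = max(1.0, config.diaphragm_ramp_cm / px)
    ramp = np.clip((rows - d_row) / ramp_px, 0.0, 1.0)
    abd_val = (
        config.body_attenuation
        + (config.abdomen_attenuation - config.body_attenuation) * ramp
    ) * ap_scale
    att = np.where(abdomen, abd_val, att)
    for side in ("left", "right"):
        att[lungs[side]] = config.lung_attenuation * ap_scale
        att[retro[side]] += config.retro_attn_extra * ap_scale
    att[heart] += config.heart_extra * ap_scale
    att[ribs] += config.rib_extra
    att[body] += config.trans_texture_sd * lowfreq[body]
    np.clip(att, 0.0, None, out=att)

    scatter = np.zeros((R, C))
    g = config.lung_texture_rel
    lung_tex = np.exp(g * granularity - 0.5 * g * g)
    gr = config.retro_texture_rel
    retro_tex = np.exp(gr * granularity - 0.5 * gr * gr)
    for side in ("left", "right"):
        m = lungs[side]
        env = 1.0 + config.envelope_amp * (0.5 - lung_rho[side][m])
        scatter[m] = config.lung_scatter * env * lung_tex[m]
        mr = retro[side]
        scatter[mr] = config.retro_scatter * retro_tex[mr]
    np.clip(scatter, 0.0, None, out=scatter)

    masks = {
        "background": ~body,
        "left_lung": lungs["left"],
        "right_lung": lungs["right"],
        "pleural_gas": np.zeros((R, C), dtype=bool),
        "retro_diaphragmatic_lung_left": retro["left"],
        "retro_diaphragmatic_lung_right": retro["right"],
        "ribs": ribs,
        "heart": heart,
        "abdomen": abdomen & ~retro["left"] & ~retro["right"],
    }
    meta = {
        "rng_seed": config.rng_seed,
        "diaphragm_row": d_row,
        "retro_band_rows": (d_row + 1, int(round(0.97 * R))),
        "lung_col_centers_px": tuple(f * C for f in config.lung_col_centers),
        "mid_col": C // 2,
    }
    return ThoraxPhantom(
        attenuation_map=att,
        scatter_map=scatter,
        masks=masks,
        truth=_truth_from_masks(masks, px),
        state="baseline",
        config=config,
        meta=meta,
    )


def lateral_gap_width_px(air_volume_ml: float, config: PhantomConfig) -> int:
    """Pleural gap width in pixels for an instilled air volume (linear map)."""
    gap_cm = config.max_gap_cm * (air_volume_ml / 500.0)
    return int(round(gap_cm / config.pixel_size_object))


def _carve_lateral_band(
    phantom: ThoraxPhantom, side: str, width_px: int
) -> np.ndarray:
    """Carve a gas band off the lateral edge of one lung; returns the band."""
    lung = phantom.masks[f"{side}_lung"]
    R, C = lung.shape
    has = lung.any(axis=1)
    col_idx = np.arange(C)[None, :]
    if side == "left":
        edge = np.argmax(lung, axis=1)  # first lung column per row
        band = lung & (col_idx < (edge + width_px)[:, None])
    else:
        edge = C - 1 - np.argmax(lung[:, ::-1], axis=1)  # last lung column
        band = lung & (col_idx > (edge - width_px)[:, None])
    band[~has] = False
    return band


def induce_pneumothorax(
    phantom: ThoraxPhantom, spec: PneumothoraxSpec
) -> ThoraxPhantom:
    """Apply a pneumothorax to a baseline phantom; the input is not modified."""
    if phantom.state != "baseline":
        raise ValueError("pneumothorax can only be induced on a baseline phantom")
    if f"{spec.side}_lung" not in phantom.masks:
        raise KeyError(f"phantom has no lung mask for side {spec.side!r}")

    out = phantom.copy()
    cfg = out.config
    ap_scale = cfg.ap_diameter / REFERENCE_AP_DIAMETER

    if spec.location == "lateral" and spec.air_volume > 0:
        width = lateral_gap_width_px(spec.air_volume, cfg)
        if width > 0:
            band = _carve_lateral_band(out, spec.side, width)
            out.scatter_map[band] = 0.0
            out.attenuation_map[band] -= (
                (cfg.lung_attenuation - cfg.gas_attenuation) * ap_scale
            )
            np.clip(out.attenuation_map, 0.0, None, out=out.attenuation_map)
            out.masks[f"{spec.side}_lung"] &= ~band
            out.masks["pleural_gas"] |= band

    if spec.collapse_fraction > 0:
        key = f"retro_diaphragmatic_lung_{spec.side}"
        retro = out.masks[key]
        n = int(retro.sum())
        k = int(round(spec.collapse_fraction * n))
        if k > 0:
            # dorsal air compresses the lung from the top (dorsal) edge;
            # argwhere is row-major, so the first k pixels are the dorsal-most
            removed = np.argwhere(retro)[:k]
            rr, cc = removed[:, 0], removed[:, 1]
            out.scatter_map[rr, cc] = 0.0
            out.attenuation_map[rr, cc] -= cfg.retro_attn_extra * ap_scale
            retro[rr, cc] = False
            out.masks["pleural_gas"][rr, cc] = True

    out.truth = _truth_from_masks(out.masks, cfg.pixel_size_object)
    out.state = "pneumothorax"
    out.meta["pneumothorax"] = dataclasses.asdict(spec)
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: study-condition distributions for the default cohort
COHORT_DEFAULTS = {
    "n_animals": 8,
    "ap_diameter_mean": 20.2,
    "ap_diameter_sd": 2.3,
    "body_mass_mean": 25.8,
    "body_mass_sd": 5.9,
    "lateral_air_ml": (200.0, 500.0),  # uniform range, laterally visible
    "dorsal_air_ml": (50.0, 150.0),  # uniform range, dorsal-only animals
    "collapse_mean": 0.205,
    "collapse_sd": 0.03,
    "retro_area_affected_mean": 62.8,  # cm^2
    "retro_area_affected_sd": 7.8,
    "retro_area_control_mean": 57.6,
    "retro_area_control_sd": 10.3,
}


@dataclass
class CohortAnimal:
    """One animal of a simulated cohort: baseline and pneumothorax phantoms."""

    animal_id: int
    params: dict
    baseline: ThoraxPhantom
    pneumothorax: ThoraxPhantom

    @property
    def in_vivo(self) -> bool:
        return bool(self.params["in_vivo"])

    @property
    def has_lateral(self) -> bool:
        return self.params["location"] == "lateral"


def draw_cohort_params(
    n_animals: int = 8, cohort_seed: int = 0, calibration: str = "paper2018"
) -> list[dict]:
    """Draw per-animal study parameters for one cohort.

    The default cohort mirrors the study conditions: 8 animals, 3 ex vivo
    (all with lateral pneumothoraces), 5 in vivo of which 3 lateral and 2
    with dorsally accumulating air only.  Every animal receives a dorsal
    collapse of the retro-diaphragmatic lung (mean fraction 0.205) since
    pleural air always rises dorsally in abdominal position.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    get_calibration(calibration)  # validate the name early
    d = COHORT_DEFAULTS
    rng = default_rng(SeedSequence([int(cohort_seed) & 0x7FFFFFFF, 0xC0110]))
    n_dorsal = n_animals // 4  # 2 of 8 by default
    n_ex_vivo = max(1, int(round(3 * n_animals / 8)))
    params = []
    for i in range(n_animals):
        dorsal_only = i >= n_animals - n_dorsal
        in_vivo = i >= n_ex_vivo  # ex-vivo animals all had lateral pneumothoraces
        side = "left" if rng.random() < 0.5 else "right"
        if dorsal_only:
            air = float(rng.uniform(*d["dorsal_air_ml"]))
        else:
            air = float(rng.uniform(*d["lateral_air_ml"]))
        collapse = float(
            np.clip(rng.normal(d["collapse_mean"], d["collapse_sd"]), 0.03, 0.5)
        )
        area_aff = float(
            np.clip(
                rng.normal(d["retro_area_affected_mean"], d["retro_area_affected_sd"]),
                38.0, 92.0,
            )
        )
        area_ctl = float(
            np.clip(
                rng.normal(d["retro_area_control_mean"], d["retro_area_control_sd"]),
                30.0, 92.0,
            )
        )
        params.append(
            {
                "animal_id": i,
                "in_vivo": in_vivo,
                "location": "dorsal" if dorsal_only else "lateral",
                "side": side,
                "air_volume": air,
                "collapse_fraction": collapse,
                "retro_area_affected": area_aff,
                "retro_area_control": area_ctl,
                "ap_diameter": float(
                    np.clip(rng.normal(d["ap_diameter_mean"], d["ap_diameter_sd"]),
                            15.0, 27.0)
                ),
                "body_mass": float(
                    np.clip(rng.normal(d["body_mass_mean"], d["body_mass_sd"]),
                            12.0, 45.0)
                ),
                "phantom_seed": int(rng.integers(0, 2**31 - 1)),
            }
        )
    return params


def generate_cohort(
    n_animals: int = 8,
    cohort_seed: int = 0,
    calibration: str = "paper2018",
    scale: str = "full",
) -> list[CohortAnimal]:
    """Generate baseline/pneumothorax phantom pairs for one cohort."""
    animals = []
    for p in draw_cohort_params(n_animals, cohort_seed, calibration):
        if p["side"] == "left":
            retro_areas = (p["retro_area_affected"], p["retro_area_control"])
        else:
            retro_areas = (p["retro_area_control"], p["retro_area_affected"])
        config = PhantomConfig.from_calibration(
            calibration,
            scale=scale,
            rng_seed=p["phantom_seed"],
            ap_diameter=p["ap_diameter"],
            body_mass=p["body_mass"],
            retro_area_cm2=retro_areas,
        )
        baseline = generate_phantom(config)
        spec = PneumothoraxSpec(
            side=p["side"],
            location=p["location"],
            air_volume=p["air_volume"] if p["location"] == "lateral" else 0.0,
            collapse_fraction=p["collapse_fraction"],
        )
        animals.append(
            CohortAnimal(
                animal_id=p["animal_id"],
                params=p,
                baseline=baseline,
                pneumothorax=induce_pneumothorax(baseline, spec),
            )
        )
    return animals
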