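"""End-to-end experiment orchestration: cohorts -> scans -> images -> tables.

This module chains the pipeline stages for whole simulated cohorts: generate
the animal phantoms, fringe-scan them (noiseless flat-field reference, Poisson
noise on the sample scans, cardiac motion artifact for in-vivo animals),
retrieve transmission/dark-field pairs, apply the quantitative filter, place
ROIs, and compute per-animal CNRs and retro-diaphragmatic projected areas.
The result is one tidy DataFrame row per animal, ready for
:func:`darkfield_thorax.stats.cohort_summary`.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.random import SeedSequence
from scipy import ndimage

from .calibration import get_calibration
from .filtering import DEFAULT_FWHM_PX, gaussian_lowpass
from .interferometer import (
    AcquisitionSettings,
    ScannerGeometry,
    SteppingScan,
    add_motion_artifact,
    simulate_reference,
    simulate_scan,
)
from .phantom import CohortAnimal, ThoraxPhantom, generate_cohort
from .retrieval import RadiographPair, retrieve
from .roi_metrics import (
    auto_cnr_rois,
    cnr,
    projected_area,
    retro_band_params,
    segment_inflated_lung,
)
from . import stats as dfstats


def _scan_seed(*keys: int) -> int:
    """Derive a sub-2^31 scan seed from a tuple of integer keys."""
    return int(SeedSequence([int(k) & 0x7FFFFFFF for k in keys]).generate_state(1)[0]
               & 0x7FFFFFFF)


def heart_edge_mask(phantom: ThoraxPhantom, width_px: int = 3) -> np.ndarray:
    """Boundary band of the heart mask, where cardiac motion artifacts arise."""
    heart = phantom.masks["heart"]
    if not heart.any():
        return np.zeros_like(heart)
    return heart ^ ndimage.binary_erosion(heart, iterations=width_px)


def image_animal(
    phantom: ThoraxPhantom,
    geometry: ScannerGeometry,
    settings: AcquisitionSettings,
    reference: SteppingScan,
    in_vivo: bool = False,
    motion_amplitude: float = 0.0,
) -> RadiographPair:
    """Simulate one exposure of a phantom and retrieve the image pair."""
    scan = simulate_scan(phantom, geometry, settings)
    if in_vivo and motion_amplitude > 0:
        scan = add_motion_artifact(scan, heart_edge_mask(phantom), motion_amplitude)
    return retrieve(scan, reference)


def animal_cnrs(
    pair: RadiographPair,
    phantom: ThoraxPhantom,
    side: str,
    roi_size_cm: float,
    margin_cm: float,
    fwhm_px: float = DEFAULT_FWHM_PX,
) -> dict[str, float]:
    """The four lung/pneumothorax CNRs of one lateral-pneumothorax exposure."""
    roi_l, roi_p = auto_cnr_rois(phantom, side, roi_size_cm, margin_cm)
    df_filt = gaussian_lowpass(pair.darkfield, fwhm_px)
    t_filt = gaussian_lowpass(pair.transmission, fwhm_px)
    return {
        "cnr_df_filtered": cnr(df_filt, roi_l, roi_p),
        "cnr_df_unfiltered": cnr(pair.darkfield, roi_l, roi_p),
        "cnr_t_unfiltered": cnr(pair.transmission, roi_l, roi_p),
        "cnr_t_filtered": cnr(t_filt, roi_l, roi_p),
    }


def animal_areas(
    pair_before: RadiographPair,
    pair_after: RadiographPair,
    animal: CohortAnimal,
    cal,
) -> dict[str, float]:
    """Segmented retro-diaphragmatic areas (cm^2) before/after induction."""
    side_aff = animal.params["side"]
    side_ctl = "right" if side_aff == "left" else "left"
    out = {}
    for tag, side in (("affected", side_aff), ("control", side_ctl)):
        params = retro_band_params(animal.baseline, side)
        for when, pair in (("before", pair_before), ("after", pair_after)):
            mask = segment_inflated_lung(
                pair.darkfield,
                side,
                params,
                threshold_factor=cal["seg_threshold_factor"],
                plateau_floor=cal["seg_plateau_floor"],
            )
            out[f"area_{tag}_{when}"] = projected_area(
                mask, params["pixel_size_object"]
            )
    return out


def run_cohort(
    cohort_seed: int = 0,
    scale: str = "full",
    calibration: str = "paper2018",
    n_animals: int = 8,
    measure_cnr: bool = True,
    measure_areas: bool = True,
    reference: SteppingScan | None = None,
) -> pd.DataFrame:
    """Image and analyze one cohort; returns one row per animal.

    CNRs are computed on the pneumothorax-state exposure of animals with a
    lateral pneumothorax; areas need both the baseline and the
    pneumothorax-state exposure of every animal.
    """
    cal = get_calibration(calibration)
    geometry = ScannerGeometry.from_calibration(calibration, scale=scale)
    base_settings = AcquisitionSettings.from_calibration(calibration)
    if reference is None:
        reference = simulate_reference(geometry, base_settings, noiseless=True)

    animals = generate_cohort(n_animals, cohort_seed, calibration, scale)
    rows = []
    for animal in animals:
        p = animal.params
        row = {
            "cohort_seed": cohort_seed,
            "animal_id": animal.animal_id,
            "in_vivo": animal.in_vivo,
            "has_lateral": animal.has_lateral,
            "side": p["side"],
            "air_volume": p["air_volume"],
            "collapse_fraction": p["collapse_fraction"],
        }
        motion = cal["motion_amplitude"] if animal.in_vivo else 0.0

        def _pair(phantom, state_key):
            settings = replace(
                base_settings,
                rng_seed=_scan_seed(cohort_seed, animal.animal_id, state_key),
            )
            return image_animal(
                phantom, geometry, settings, reference,
                in_vivo=animal.in_vivo, motion_amplitude=motion,
            )

        pair_after = _pair(animal.pneumothorax, 1)
        if measure_cnr and animal.has_lateral:
            row.update(
                animal_cnrs(
                    pair_after,
                    animal.pneumothorax,
                    p["side"],
                    cal["roi_size_cm"],
                    cal["roi_margin_cm"],
                )
            )
        if measure_areas:
            pair_before = _pair(animal.baseline, 0)
            row.update(animal_areas(pair_before, pair_after, animal, cal))
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(
    n_cohorts: int = 20,
    base_seed: int = 0,
    scale: str = "full",
    calibration: str = "paper2018",
    n_animals: int = 8,
    measure_cnr: bool = True,
    measure_areas: bool = True,
) -> pd.DataFrame:
    """Run several independently seeded cohorts and stack their tables."""
    geometry = ScannerGeometry.from_calibration(calibration, scale=scale)
    settings = AcquisitionSettings.from_calibration(calibration)
    reference = simulate_reference(geometry, settings, noiseless=True)
    frames = []
    for i in range(n_cohorts):
        frames.append(
            run_cohort(
                cohort_seed=_scan_seed(base_seed, 0xC0F0, i),
                scale=scale,
                calibration=calibration,
                n_animals=n_animals,
                measure_cnr=measure_cnr,
                measure_areas=measure_areas,
                reference=reference,
            ).assign(cohort=i)
        )
    return pd.concat(frames, ignore_index=True)


def grand_mean_cnrs(study: pd.DataFrame) -> dict[str, float]:
    """Grand-mean CNRs over all lateral animals of a multi-cohort study."""
    lateral = study[study["has_lateral"]]
    return {
        col: float(lateral[col].dropna().mean())
        for col in dfstats.CNR_COLUMNS.values()
        if col in lateral.columns
    }


def area_change_summary(study: pd.DataFrame) -> dict:
    """Mean per-animal percent area changes and per-cohort paired p-values."""
    out = {}
    for side in ("affected", "control"):
        pct = dfstats.percent_change(
            study[f"area_{side}_before"], study[f"area_{side}_after"]
        )
        out[f"{side}_mean_percent_change"] = float(np.mean(pct))
    pvals = []
    for _, grp in study.groupby("cohort_seed"):
        res = dfstats.paired_ttest(
            grp["area_affected_before"], grp["area_affected_after"]
        )
        pvals.append(res.p)
    out["affected_p_values"] = pvals
    return out


# ---------------------------------------------------------------------------
# full experiment with on-disk report
# ---------------------------------------------------------------------------

DEFAULT_EXPERIMENT_CONFIG = {
    "calibration": "paper2018",
    "scale": "full",
    "n_cohorts": 1,
    "n_animals": 8,
    "seed": 0,
    "save_images": False,
}


def run_experiment(config: dict | str | Path, outdir: str | Path) -> Path:
    """Run the full experiment described by a config and write a report.

    ``config`` is a mapping or the path of a YAML file with (a subset of)
    the keys in :data:`DEFAULT_EXPERIMENT_CONFIG`.  Writes ``results.csv``
    (one row per animal), ``summary.txt``, and ``manifest.yaml`` with every
    seed; identical configs produce bit-identical CSVs.
    """
    import yaml

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_EXPERIMENT_CONFIG)
    unknown = set(config) - set(cfg)
    if unknown:
        raise ValueError(f"unknown experiment config keys: {sorted(unknown)}")
    cfg.update(config)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    study = run_study(
        n_cohorts=cfg["n_cohorts"],
        base_seed=cfg["seed"],
        scale=cfg["scale"],
        calibration=cfg["calibration"],
        n_animals=cfg["n_animals"],
    )
    study.to_csv(outdir / "results.csv", index=False)

    lines = []
    for seed, grp in study.groupby("cohort_seed"):
        summary = dfstats.cohort_summary(grp)
        lines.append(f"# cohort seed {seed}")
        lines.append(dfstats.summary_to_text(summary))
    if cfg["n_cohorts"] > 1:
        lines.append("# grand means over cohorts")
        for col, val in grand_mean_cnrs(study).items():
            lines.append(f"  {col}: {val:.3f}")
        ac = area_change_summary(study)
        lines.append(
            f"  affected area change: {ac['affected_mean_percent_change']:+.1f}%"
        )
        lines.append(
            f"  control area change: {ac['control_mean_percent_change']:+.1f}%"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")

    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "config": cfg,
                "cohort_seeds": sorted(study["cohort_seed"].unique().tolist()),
            },
            fh,
        )

    if cfg["save_images"]:
        from . import io as dfio

        cohort = generate_cohort(
            cfg["n_animals"], _scan_seed(cfg["seed"], 0xC0F0, 0),
            cfg["calibration"], cfg["scale"],
        )
        for animal in cohort:
            dfio.write_phantom(
                animal.pneumothorax, outdir / f"animal{animal.animal_id:02d}"
            )
    return outdir
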