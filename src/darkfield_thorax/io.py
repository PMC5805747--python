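"""On-disk formats: 32-bit float TIFFs for maps/images, YAML sidecars, CSV.

Phantom maps and retrieved images are written as one 32-bit float TIFF per
map; label masks as an 8-bit labeled TIFF plus a JSON label dictionary;
stepping scans as a multi-page 32-bit TIFF with a YAML sidecar holding the
scan phases and seeds.  Every writer logs the seed it was given through the
sidecar/metadata files so runs can be reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .interferometer import AcquisitionSettings, ScannerGeometry, SteppingScan
from .phantom import MASK_LABELS, PhantomConfig, ThoraxPhantom
from .retrieval import RadiographPair


def _f32(arr: np.ndarray) -> np.ndarray:
    return np.asarray(arr, dtype=np.float32)


def write_phantom(phantom: ThoraxPhantom, outdir: str | Path) -> Path:
    """Write maps, labeled masks + JSON labels, truth CSV and config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "attenuation.tif", _f32(phantom.attenuation_map))
    tifffile.imwrite(outdir / "scatter.tif", _f32(phantom.scatter_map))

    labels = {name: i for i, name in enumerate(MASK_LABELS)}
    labeled = np.zeros(phantom.grid_shape, dtype=np.uint8)
    for name, code in labels.items():  # later labels overwrite earlier overlaps
        if name in phantom.masks:
            labeled[phantom.masks[name]] = code
    tifffile.imwrite(outdir / "masks.tif", labeled)
    (outdir / "mask_labels.json").write_text(json.dumps(labels, indent=1))

    with open(outdir / "truth.csv", "w") as fh:
        fh.write("region,area_cm2\n")
        for key, val in phantom.truth.items():
            fh.write(f"{key},{val:.6f}\n")
    with open(outdir / "phantom.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "state": phantom.state,
                "rng_seed": int(phantom.config.rng_seed),
                "pixel_size_object_cm": phantom.config.pixel_size_object,
                "grid_shape": list(phantom.grid_shape),
                "meta": _yaml_safe(phantom.meta),
            },
            fh,
        )
    return outdir


def write_scan(scan: SteppingScan, path: str | Path) -> Path:
    """Multi-page 32-bit TIFF plus a YAML sidecar (phases, seed, geometry)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, _f32(scan.frames))
    sidecar = {
        "phases": [float(p) for p in scan.phases],
        "is_reference": scan.is_reference,
        "rng_seed": int(scan.settings.rng_seed),
        "n_steps": int(scan.settings.n_steps),
        "photons_per_step": scan.settings.photons_per_step,
        "fringe_period_rows": scan.settings.fringe_period_rows,
        "v0": scan.geometry.v0,
        "effective_pixel_um": scan.geometry.effective_pixel_um,
        "provenance": _yaml_safe(scan.provenance),
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh)
    return path


def read_scan(path: str | Path) -> SteppingScan:
    """Read a stepping scan written by :func:`write_scan`."""
    path = Path(path)
    frames = tifffile.imread(path).astype(np.float64)
    with open(path.with_suffix(".yaml")) as fh:
        side = yaml.safe_load(fh)
    eff_um = side["effective_pixel_um"]
    geometry = ScannerGeometry(
        v0=side["v0"],
        effective_pixel_um=eff_um,
        true_pixel_um=444.0 / 360.0 * eff_um,
    )
    settings = AcquisitionSettings(
        n_steps=side["n_steps"],
        photons_per_step=side["photons_per_step"],
        fringe_period_rows=side["fringe_period_rows"],
        rng_seed=side["rng_seed"],
    )
    return SteppingScan(
        frames=frames,
        phases=np.asarray(side["phases"], dtype=float),
        geometry=geometry,
        settings=settings,
        is_reference=side["is_reference"],
        provenance=side.get("provenance", {}),
    )


def write_pair(pair: RadiographPair, outdir: str | Path) -> Path:
    """Write retrieved transmission/dark-field images and masks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "transmission.tif", _f32(pair.transmission))
    tifffile.imwrite(outdir / "darkfield.tif", _f32(pair.darkfield))
    tifffile.imwrite(outdir / "phase.tif", _f32(pair.phase))
    tifffile.imwrite(outdir / "gap_mask.tif", pair.gap_mask.astype(np.uint8))
    with open(outdir / "pair.yaml", "w") as fh:
        yaml.safe_dump({"provenance": _yaml_safe(pair.provenance)}, fh)
    return outdir


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _yaml_safe(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
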