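"""Frozen parameter sets coupling the phantom, scanner and analysis defaults.

A *calibration* bundles everything that trades off against everything else in
the simulated imaging chain: tissue line integrals, anatomical-texture
amplitudes and correlation lengths, fringe visibility, photon fluence, and the
segmentation threshold.  The named set ``paper2018`` is tuned (by forward
simulation of full-resolution cohorts, then frozen) so that ROI statistics of
the retrieved radiographs reproduce the quantitative behaviour of the 2018
large-animal pneumothorax study this pipeline models: lung/pleural-gas CNRs of
roughly 3.7 / 2.5 in filtered / unfiltered dark-field and 1.1 in transmission,
and a ~20 % loss of retro-diaphragmatic projected lung area after a unilateral
pneumothorax.

Values are plain floats; a calibration is read-only by convention.
"""

from __future__ import annotations

from types import MappingProxyType

#: Calibration registry.  Keys of each entry:
#:
#: phantom contrast (all are dimensionless line integrals, -ln of the ideal
#: transmitted / visibility-preserved fraction):
#:   body_attenuation        soft-tissue chest wall path
#:   lung_attenuation        inflated-lung path (lower density)
#:   gas_attenuation         chest wall + free pleural air path
#:   rib_extra               additive bone contribution inside rib bands
#:   heart_extra             additive mediastinal contribution
#:   abdomen_attenuation     retro-diaphragmatic soft tissue path
#:   retro_attn_extra        additive lung contribution behind the diaphragm
#:   lung_scatter            mean dark-field line integral of inflated lung
#:   retro_scatter           same, for the retro-diaphragmatic lung
#:
#: anatomical noise (texture):
#:   lung_texture_rel        lognormal sigma of lung scatter granularity
#:   retro_texture_rel       same, retro-diaphragmatic lung
#:   lung_texture_corr_px    granularity correlation length [px at 360 um]
#:   trans_texture_sd        additive sd of low-frequency attenuation field
#:   trans_texture_corr_px   its correlation length [px at 360 um]
#:   envelope_amp            smooth centre-to-edge modulation of lung scatter
#:
#: acquisition:
#:   v0                      reference fringe visibility
#:   photons_per_step        expected photons / pixel / phase step
#:   n_steps                 phase samples over one fringe period
#:   fringe_period_rows      vertical period of the flat-field fringe phase [px]
#:   motion_amplitude        relative stepping-curve perturbation at heart edge
#:
#: analysis:
#:   seg_threshold_factor    dark-field threshold as fraction of gas plateau
#:   seg_plateau_floor       minimum D counted as plateau when estimating it
#:   roi_size_cm             edge length of the square lung ROI
#:   roi_margin_cm           erosion margin applied to ROI source masks
_PAPER2018 = {
    # contrast
    "body_attenuation": 1.60,
    "lung_attenuation": 0.80,
    "gas_attenuation": 0.732,
    "rib_extra": 0.50,
    "heart_extra": 0.40,
    "abdomen_attenuation": 1.80,
    "retro_attn_extra": 0.20,
    "lung_scatter": 0.357,
    "retro_scatter": 0.60,
    # texture
    "lung_texture_rel": 0.385,
    "retro_texture_rel": 0.10,
    "lung_texture_corr_px": 6.0,
    "trans_texture_sd": 0.060,
    "trans_texture_corr_px": 12.0,
    "envelope_amp": 0.12,
    # acquisition
    "v0": 0.25,
    "photons_per_step": 2500.0,
    "n_steps": 8,
    "fringe_period_rows": 16.0,
    "motion_amplitude": 0.004,
    # analysis
    "seg_threshold_factor": 0.70,
    "seg_plateau_floor": 0.80,
    "roi_size_cm": 2.0,
    "roi_margin_cm": 0.11,
}

CALIBRATIONS = {"paper2018": MappingProxyType(_PAPER2018)}


def get_calibration(name: str = "paper2018"):
    """Return the frozen calibration mapping registered under *name*."""
    try:
        return CALIBRATIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown calibration {name!r}; available: {sorted(CALIBRATIONS)}"
        ) from None
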