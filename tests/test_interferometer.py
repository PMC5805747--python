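"""Fringe-scan forward model: stepping curves, noise, artifacts, tile gaps."""

import dataclasses

import numpy as np
import pytest

from darkfield_thorax.interferometer import (
    AcquisitionSettings,
    ScannerGeometry,
    add_motion_artifact,
    add_tile_gaps,
    simulate_reference,
    simulate_scan,
)
from darkfield_thorax.retrieval import retrieve


def test_noiseless_reference_traces_the_stepping_curve():
    """Frame means follow I0 (1 + v0 cos(phi_k)) exactly without noise."""
    geo = ScannerGeometry(v0=0.25)
    st = AcquisitionSettings(n_steps=8, photons_per_step=None)
    scan = simulate_reference(geo, st, grid_shape=(160, 144))
    # row 0 has fringe phase 0, so its series is I0 (1 + v0 cos(phi_k))
    expected = 1.0 * (1.0 + 0.25 * np.cos(scan.phases))
    assert np.allclose(scan.frames[:, 0, :], expected[:, None])
    # averaged over a whole fringe period the modulation cancels
    period = int(st.fringe_period_rows)
    assert scan.frames[:, :period, :].mean() == pytest.approx(1.0, rel=1e-12)


def test_zero_visibility_gives_flat_frames():
    geo = ScannerGeometry(v0=1e-9)
    st = AcquisitionSettings(photons_per_step=None)
    scan = simulate_reference(geo, st, grid_shape=(140, 130))
    assert np.allclose(scan.frames, 1.0, atol=1e-8)


def test_n_steps_below_three_rejected():
    with pytest.raises(ValueError, match="n_steps"):
        AcquisitionSettings(n_steps=2)


def test_poisson_counting_statistics():
    """Relative sd of the per-pixel step-mean is 1/sqrt(n I0) for a flat field."""
    geo = ScannerGeometry(v0=0.25)
    st = AcquisitionSettings(n_steps=8, photons_per_step=1e4, rng_seed=7)
    scan = simulate_reference(geo, st, grid_shape=(160, 160))
    # equally spaced phases: the cosine cancels, every pixel expects I0
    means = scan.frames.mean(axis=0)
    rel_sd = means.std() / means.mean()
    assert rel_sd == pytest.approx(1.0 / np.sqrt(8 * 1e4), rel=0.05)


def test_seeded_scans_reproduce_bit_identically(smoke_phantom, smoke_geometry):
    st = AcquisitionSettings(photons_per_step=500.0, rng_seed=11)
    a = simulate_scan(smoke_phantom, smoke_geometry, st)
    b = simulate_scan(smoke_phantom, smoke_geometry, st)
    assert np.array_equal(a.frames, b.frames)
    c = simulate_scan(
        smoke_phantom, smoke_geometry, dataclasses.replace(st, rng_seed=12)
    )
    assert not np.array_equal(a.frames, c.frames)


def test_empty_phantom_scan_equals_reference(smoke_phantom, smoke_geometry,
                                             noiseless_settings):
    empty = smoke_phantom.copy()
    empty.attenuation_map = np.zeros_like(empty.attenuation_map)
    empty.scatter_map = np.zeros_like(empty.scatter_map)
    scan = simulate_scan(empty, smoke_geometry, noiseless_settings)
    ref = simulate_reference(smoke_geometry, noiseless_settings)
    assert np.allclose(scan.frames, ref.frames)


def test_scatter_halves_modulation_not_mean(smoke_geometry, smoke_phantom,
                                            noiseless_settings):
    """scatter = ln 2 halves the fitted modulation and keeps the step mean."""
    ph = smoke_phantom.copy()
    ph.attenuation_map = np.zeros_like(ph.attenuation_map)
    ph.scatter_map = np.full_like(ph.scatter_map, np.log(2.0))
    scan = simulate_scan(ph, smoke_geometry, noiseless_settings)
    ref = simulate_reference(smoke_geometry, noiseless_settings)
    assert np.allclose(scan.frames.mean(axis=0), ref.frames.mean(axis=0))
    pair = retrieve(scan, ref)
    assert np.allclose(pair.darkfield, 0.5, atol=1e-12)


def test_energy_bookkeeping(smoke_phantom, smoke_geometry, noiseless_settings):
    """Noiseless step-mean is I0 T per pixel, independent of D and v0."""
    scan = simulate_scan(smoke_phantom, smoke_geometry, noiseless_settings)
    T = np.exp(-smoke_phantom.attenuation_map)
    assert np.allclose(scan.frames.mean(axis=0), T, rtol=1e-12)


def test_grid_mismatch_rejected(smoke_phantom, noiseless_settings):
    geo = ScannerGeometry.from_calibration(scale="half")
    with pytest.raises(ValueError, match="grid"):
        simulate_scan(smoke_phantom, geo, noiseless_settings)


class TestMotionArtifact:
    def _scan(self, smoke_phantom, smoke_geometry, noiseless_settings):
        return simulate_scan(smoke_phantom, smoke_geometry, noiseless_settings)

    def test_zero_amplitude_is_identity(self, smoke_phantom, smoke_geometry,
                                        noiseless_settings):
        scan = self._scan(smoke_phantom, smoke_geometry, noiseless_settings)
        mask = np.zeros(scan.grid_shape, dtype=bool)
        mask[50:60, 100:110] = True
        out = add_motion_artifact(scan, mask, 0.0)
        assert out is scan

    def test_streaks_confined_to_mask_rows(self, smoke_phantom, smoke_geometry,
                                           noiseless_settings):
        """Retrieved dark-field deviates only in rows crossing the edge mask."""
        scan = self._scan(smoke_phantom, smoke_geometry, noiseless_settings)
        ref = simulate_reference(smoke_geometry, noiseless_settings)
        mask = np.zeros(scan.grid_shape, dtype=bool)
        mask[60:64, 110:130] = True
        perturbed = add_motion_artifact(scan, mask, amplitude=0.05)
        clean = retrieve(scan, ref).darkfield
        streaked = retrieve(perturbed, ref).darkfield
        delta = np.abs(streaked - clean)
        rows_hit = np.nonzero(delta.max(axis=1) > 1e-9)[0]
        assert len(rows_hit) > 0
        assert set(rows_hit) <= set(range(60, 64))
        # horizontal bands: the streak extends well beyond the mask columns
        assert (delta[61] > 1e-9).sum() > (130 - 110)

    def test_ex_vivo_application_warns_but_applies(self, smoke_phantom,
                                                   smoke_geometry,
                                                   noiseless_settings):
        scan = self._scan(smoke_phantom, smoke_geometry, noiseless_settings)
        mask = np.zeros(scan.grid_shape, dtype=bool)
        mask[40:42, 50:60] = True
        with pytest.warns(UserWarning, match="ex-vivo"):
            out = add_motion_artifact(scan, mask, 0.05, ex_vivo=True)
        assert not np.array_equal(out.frames, scan.frames)


class TestTileGaps:
    def test_empty_spec_is_identity(self, smoke_phantom, smoke_geometry,
                                    noiseless_settings):
        scan = simulate_scan(smoke_phantom, smoke_geometry, noiseless_settings)
        assert add_tile_gaps(scan, []) is scan

    def test_gap_strip_masks_retrieval(self, smoke_phantom, smoke_geometry,
                                       noiseless_settings):
        scan = simulate_scan(smoke_phantom, smoke_geometry, noiseless_settings)
        ref = simulate_reference(smoke_geometry, noiseless_settings)
        gapped = add_tile_gaps(scan, [{"axis": "rows", "start": 30, "stop": 34}])
        pair = retrieve(gapped, ref)
        assert pair.gap_mask[30:34].all()
        assert np.isnan(pair.darkfield[30:34]).all()
        assert not pair.gap_mask[40:].any()
        assert np.isfinite(pair.darkfield[40:]).all()
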