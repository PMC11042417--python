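"""Shared fixtures: phantoms, property fields, and the (expensive) driven
forward studies reused across test modules."""

import numpy as np
import pytest

from spectre_eeg import forward_sim as fsim
from spectre_eeg import spectre_inverse as sinv
from spectre_eeg import tissue_model as tmod


@pytest.fixture(scope="session")
def phantom48():
    return tmod.make_phantom_head((48, 48, 48), 2.0, 0.1, seed=1)


@pytest.fixture(scope="session")
def fields48(phantom48):
    return tmod.build_property_fields(phantom48)


@pytest.fixture(scope="session")
def sensors64(phantom48):
    return fsim.place_electrodes(phantom48, 64, seed=1)


def _band_power_truth(field, fs, f_lo, f_hi):
    n = field.n_times
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (freqs >= f_lo) & (freqs < f_hi) & (freqs > 0)
    coeffs = np.fft.rfft(field.phi, axis=-1)[..., sel] * (2.0 / n)
    return np.sum(np.abs(coeffs) ** 2, axis=-1)


@pytest.fixture(scope="session")
def deep_study(phantom48, fields48, sensors64):
    """One noiseless 10 Hz source deep in white matter, 64 electrodes."""
    grid, fields, sensors = phantom48, fields48, sensors64
    src_mm = (10.0, 6.0, -4.0)
    duration, fs = 0.6, 250.0
    field, rec = fsim.synthesize_study(
        grid,
        fields,
        [fsim.OscillatorySource(src_mm, 10.0, 1.0)],
        duration,
        fs,
        sensors,
        seed=1,
    )
    return {
        "grid": grid,
        "fields": fields,
        "sensors": sensors,
        "field": field,
        "rec": rec,
        "fs": fs,
        "duration": duration,
        "src_mm": np.asarray(src_mm),
        "src_vox": np.round(grid.world_to_voxel(np.asarray(src_mm))[0]).astype(int),
        "gt_band_power": _band_power_truth(field, fs, 8.0, 12.0),
    }


@pytest.fixture(scope="session")
def small32():
    grid = tmod.make_phantom_head((32, 32, 32), 2.0, 0.1, seed=2)
    fields = tmod.build_property_fields(grid)
    sensors = fsim.place_electrodes(grid, 32, seed=2)
    return grid, fields, sensors


@pytest.fixture(scope="session")
def shallow_study32(small32):
    """A superficial gray-matter source on the small phantom (used for the
    noise-robustness property, where the clean pipeline has real signal)."""
    grid, fields, sensors = small32
    gm = np.argwhere(grid.labels == tmod.GM)
    c = np.asarray(grid.shape) / 2
    sv = gm[np.argmax(np.abs(gm - c).sum(axis=1))]
    src_mm = grid.voxel_to_world(sv)[0]
    duration, fs = 0.6, 125.0
    field, rec = fsim.synthesize_study(
        grid,
        fields,
        [fsim.OscillatorySource(src_mm, 10.0, 1.0)],
        duration,
        fs,
        sensors,
        seed=3,
    )
    return {
        "grid": grid,
        "fields": fields,
        "sensors": sensors,
        "field": field,
        "rec": rec,
        "fs": fs,
        "src_mm": src_mm,
        "gt_band_power": _band_power_truth(field, fs, 8.0, 12.0),
    }


def band_power_of_reconstruction(study, rec=None, **cfg_kwargs):
    """Run the band inverse on a study and return its band-power map."""
    sp = sinv.reconstruct_band(
        rec if rec is not None else study["rec"],
        study["grid"],
        study["fields"],
        sinv.BandSpec(8.0, 12.0),
        sinv.ReconstructionConfig(**cfg_kwargs),
    )
    return sinv.band_power_map(sp)
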