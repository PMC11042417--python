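"""File formats and run configuration.

Conventions: volumes are NIfTI-1 with the affine carrying all cross-file
geometry (world coordinates are always mm); electrode tables are TSV with
columns name/x/y/z; recordings are TSV (a time column plus one column per
channel) with a JSON sidecar holding the sampling rate and reference, or an
EDF file (read-only, via mne when available).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .forward_sim import EEGRecording, SensorArray
from .tissue_model import (
    TissueGrid,
    TissueProperties,
    TissuePropertyTable,
)
from .wetcow_dynamics import WaveField

logger = logging.getLogger(__name__)


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    data = np.asarray(data)
    if np.iscomplexobj(data):
        raise IOError_("save complex volumes as real+imag or mag/phase pairs")
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine))
    nib.save(img, str(path))


def load_volume(path) -> Tuple[np.ndarray, np.ndarray]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise IOError_(f"cannot read NIfTI volume {path}: {exc}") from exc
    return np.asarray(img.dataobj), img.affine


def save_grid(grid: TissueGrid, path) -> None:
    img = nib.Nifti1Image(grid.labels.astype(np.int16), grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size))
    nib.save(img, str(path))


def load_grid(path) -> TissueGrid:
    data, affine = load_volume(path)
    voxel_size = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    return TissueGrid(np.asarray(data, dtype=np.int16), voxel_size, affine)


def save_complex_volume(
    data: np.ndarray, affine: np.ndarray, path, style: str = "reim"
) -> None:
    """Write a complex volume as a NIfTI pair.

    ``reim`` writes <stem>_real/<stem>_imag; ``magphase`` writes
    <stem>_mag/<stem>_phase.
    """
    path = Path(path)
    stem = path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    ext = path.name[len(stem):] or ".nii.gz"
    if style == "reim":
        parts = {"real": np.real(data), "imag": np.imag(data)}
    elif style == "magphase":
        parts = {"mag": np.abs(data), "phase": np.angle(data)}
    else:
        raise IOError_("style must be 'reim' or 'magphase'")
    for tag, arr in parts.items():
        save_volume(arr, affine, path.with_name(f"{stem}_{tag}{ext}"))


def save_wave_field(field: WaveField, path) -> None:
    """4D NIfTI (space x time) with dt recorded in the time zoom and a JSON
    sidecar."""
    affine = field.affine if field.affine is not None else np.eye(4)
    img = nib.Nifti1Image(np.asarray(np.real(field.phi), dtype=np.float64), affine)
    zooms = tuple(field.spacing * 1e3) + (field.dt,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps({"dt": field.dt}))


def load_wave_field(path) -> WaveField:
    data, affine = load_volume(path)
    if data.ndim != 4:
        raise IOError_("wave field file must be 4D")
    side = _sidecar_path(path)
    if side.exists():
        dt = float(json.loads(side.read_text())["dt"])
    else:
        dt = float(nib.load(str(path)).header.get_zooms()[3])
    voxel_mm = np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))
    return WaveField(
        phi=np.asarray(data, float), dt=dt, spacing=voxel_mm * 1e-3, affine=affine
    )


def _sidecar_path(path) -> Path:
    path = Path(path)
    name = path.name
    for suf in (".nii.gz", ".nii", ".tsv", ".csv"):
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    return path.with_name(name + ".json")


# ---------------------------------------------------------------------------
# electrodes and recordings
# ---------------------------------------------------------------------------

def save_electrodes(sensors: SensorArray, path) -> None:
    df = pd.DataFrame(
        {
            "name": sensors.names,
            "x": sensors.positions[:, 0],
            "y": sensors.positions[:, 1],
            "z": sensors.positions[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_electrodes(path) -> SensorArray:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "x", "y", "z"}
    if not required <= set(df.columns):
        raise IOError_(
            f"electrode table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    names = [str(n) for n in df["name"]]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise IOError_(f"duplicate electrode names: {dupes}")
    return SensorArray(names=names, positions=df[["x", "y", "z"]].to_numpy(float))


def save_recording(rec: EEGRecording, path) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    cols = {"time": t}
    for i, name in enumerate(rec.sensors.names):
        cols[name] = rec.data[i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    _sidecar_path(path).write_text(
        json.dumps({"fs": rec.fs, "reference": rec.sensors.reference})
    )


def load_recording(path, electrodes: Optional[SensorArray] = None) -> EEGRecording:
    """Load a TSV/CSV (+ JSON sidecar) or EDF recording.

    When an electrode table is supplied, channel names must agree between
    the two files (the error lists the symmetric difference) and channels
    are reordered to the electrode order.  Without one, sensor positions
    are marked unknown (NaN).
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        names, data, fs, reference = _read_edf(path)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
        if "time" not in df.columns:
            raise IOError_("recording table needs a 'time' column")
        names = [c for c in df.columns if c != "time"]
        data = df[names].to_numpy(float).T
        side = _sidecar_path(path)
        if not side.exists():
            raise IOError_(f"missing sampling-rate sidecar {side}")
        meta = json.loads(side.read_text())
        if "fs" not in meta:
            raise IOError_(f"sidecar {side} lacks 'fs'")
        fs = float(meta["fs"])
        reference = meta.get("reference", "none")

    if electrodes is not None:
        rec_set, ele_set = set(names), set(electrodes.names)
        if rec_set != ele_set:
            raise IOError_(
                "channel names differ between recording and electrode table; "
                f"symmetric difference: {sorted(rec_set ^ ele_set)}"
            )
        order = [names.index(n) for n in electrodes.names]
        data = data[order]
        sensors = SensorArray(
            names=list(electrodes.names),
            positions=electrodes.positions,
            reference=reference,
        )
    else:
        sensors = SensorArray(
            names=names,
            positions=np.full((len(names), 3), np.nan),
            reference=reference,
        )
    return EEGRecording(data=data, fs=fs, sensors=sensors)


def _read_edf(path):
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise IOError_("EDF reading requires the optional mne dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return (
        list(raw.ch_names),
        raw.get_data(),
        float(raw.info["sfreq"]),
        "none",
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Structured run configuration (YAML), CLI flags override."""

    labels: Optional[str] = None
    electrodes: Optional[str] = None
    recording: Optional[str] = None
    out_dir: str = "."
    bands: List[Tuple[float, float]] = field(default_factory=lambda: [(8.0, 12.0)])
    iterations: int = 10
    tol: float = 1e-6
    seed_splat_fwhm: float = 3.0
    smooth_width: Optional[float] = None
    property_table: TissuePropertyTable = field(
        default_factory=TissuePropertyTable.default
    )
    seed: int = 0
    log_level: str = "INFO"


_LABEL_BY_NAME = {"background": 0, "scalp": 1, "skull": 2, "csf": 3, "gm": 4, "wm": 5}


def property_table_from_dict(d: Dict) -> TissuePropertyTable:
    table = TissuePropertyTable.default()
    for key, entry in d.items():
        lab = _LABEL_BY_NAME.get(str(key).lower())
        if lab is None:
            raise IOError_(f"unknown tissue name {key!r} in property table")
        base = table.entries[lab]
        table.entries[lab] = TissueProperties(
            sigma=float(entry.get("sigma", base.sigma)),
            eps_rel=float(entry.get("eps_rel", base.eps_rel)),
            anisotropy_ratio=float(
                entry.get("anisotropy_ratio", base.anisotropy_ratio)
            ),
        )
    return table


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    simple = {
        "labels",
        "electrodes",
        "recording",
        "out_dir",
        "iterations",
        "tol",
        "seed_splat_fwhm",
        "smooth_width",
        "seed",
        "log_level",
    }
    for key, val in raw.items():
        if key in simple:
            setattr(cfg, key, val)
        elif key == "bands":
            cfg.bands = [(float(lo), float(hi)) for lo, hi in val]
        elif key == "properties":
            cfg.property_table = property_table_from_dict(val)
        else:
            raise IOError_(f"unknown config key {key!r}")
    for attr in ("labels", "electrodes", "recording"):
        p = getattr(cfg, attr)
        if p is not None and not Path(p).exists():
            raise IOError_(f"config path for {attr!r} does not exist: {p}")
    return cfg
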