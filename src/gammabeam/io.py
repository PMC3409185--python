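"""File formats and configuration.

Epoch container (HDF5, format version ``1.0``)::

    /data                (n_epochs, n_ch, n_samples) float64, tesla
    /time_ms             (n_samples,) float64
    /labels              (n_epochs,) UTF-8 strings
    /rejected            (n_epochs,) bool
    /sensors/positions   (n_ch, 3) float64, meters
    /sensors/orientations(n_ch, 3) float64, unit vectors
    /head/center         (3,) float64, meters
    /head/radius         () float64, meters
    /affine              (4, 4) float64, subject <-> MNI (mm)
    /covariates/<name>   () float64

Volumetric maps export to NIfTI on the grid bounding box with an affine
that reproduces MNI mm coordinates; peak tables and behavioral data are
CSV; TF maps are HDF5 with explicit axes; analysis configs are YAML
validated by a pydantic schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import SchemaError
from .forward import HeadModel, SensorArray, SourceGrid
from .preprocess import EpochSet
from .simulate import SubjectRecord

FORMAT_VERSION = "1.0"


# ---------------------------------------------------------------- epochs

def write_epochs(record: SubjectRecord, path, sensors: SensorArray | None = None,
                 head: HeadModel | None = None) -> None:
    """Serialize a SubjectRecord to the documented HDF5 layout.

    Sensor geometry and head model are embedded when provided so a
    container is self-describing for source analysis.
    """
    if record.epochs is None:
        raise SchemaError("record has no epoch data to write")
    ep = record.epochs
    with h5py.File(path, "w") as f:
        if sensors is not None and head is not None:
            write_sensor_geometry(f, sensors, head)
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["subject_id"] = record.subject_id
        f.attrs["group"] = record.group
        f.attrs["sampling_rate"] = ep.sampling_rate
        f.create_dataset("data", data=ep.data)
        f.create_dataset("time_ms", data=ep.time_ms)
        f.create_dataset(
            "labels",
            data=np.asarray(ep.condition_labels, dtype="S32"),
        )
        f.create_dataset("rejected", data=ep.rejected_mask)
        f.create_dataset("affine", data=record.affine)
        cov = f.create_group("covariates")
        for k, v in record.covariates.items():
            cov.create_dataset(k, data=float(v))


def write_sensor_geometry(f, sensors: SensorArray, head: HeadModel) -> None:
    g = f.create_group("sensors")
    g.create_dataset("positions", data=sensors.positions)
    g.create_dataset("orientations", data=sensors.orientations)
    h = f.create_group("head")
    h.create_dataset("center", data=head.center)
    h.create_dataset("radius", data=head.radius)


def _require(f, name: str):
    if name not in f:
        raise SchemaError(f"missing dataset {name!r}")
    return f[name]


def read_epochs(path) -> SubjectRecord:
    """Read a SubjectRecord back; schema violations raise SchemaError."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SchemaError(f"not a readable HDF5 container: {exc}") from exc
    with f:
        version = str(f.attrs.get("format_version", ""))
        if not version:
            raise SchemaError("missing format_version attribute")
        if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
            raise SchemaError(f"unknown major format version {version!r}")
        data = _require(f, "data")[()]
        time_ms = _require(f, "time_ms")[()]
        labels = _require(f, "labels")[()].astype(str)
        rejected = _require(f, "rejected")[()]
        affine = _require(f, "affine")[()]
        if data.ndim != 3:
            raise SchemaError("/data must be epochs x channels x samples")
        if time_ms.shape[0] != data.shape[2]:
            raise SchemaError("/time_ms length does not match /data")
        if labels.shape[0] != data.shape[0]:
            raise SchemaError("/labels length does not match /data")
        if affine.shape != (4, 4):
            raise SchemaError("/affine must be 4x4")
        covariates = {}
        if "covariates" in f:
            covariates = {k: float(f["covariates"][k][()])
                          for k in f["covariates"]}
        epochs = EpochSet(
            data=data,
            sampling_rate=float(f.attrs["sampling_rate"]),
            time_ms=time_ms,
            condition_labels=labels,
            rejected_mask=rejected,
        )
        return SubjectRecord(
            subject_id=str(f.attrs.get("subject_id", "unknown")),
            group=str(f.attrs.get("group", "unknown")),
            epochs=epochs,
            affine=affine,
            covariates=covariates,
            true_params={},
        )


def read_sensor_geometry(path) -> tuple[SensorArray, HeadModel]:
    """Sensor array and head model embedded in an epoch container."""
    with h5py.File(path, "r") as f:
        if "sensors" not in f or "head" not in f:
            raise SchemaError("container carries no sensor geometry")
        pos = f["sensors/positions"][()]
        ori = f["sensors/orientations"][()]
        sensors = SensorArray(pos, ori,
                              tuple(f"MAG{k:03d}" for k in range(len(pos))))
        head = HeadModel(center=f["head/center"][()],
                         radius=float(f["head/radius"][()]))
    return sensors, head


def read_affine_text(path) -> np.ndarray:
    """4x4 affine from 4-line whitespace-delimited text."""
    aff = np.loadtxt(path)
    if aff.shape != (4, 4):
        raise SchemaError(f"affine file {path} is not 4x4")
    return aff


def write_affine_text(affine: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(affine, dtype=float), fmt="%.12g")


# ------------------------------------------------------------- stat maps

def grid_to_volume(grid: SourceGrid, values: np.ndarray):
    """Dense volume plus NIfTI affine for a lattice of grid values."""
    pts = grid.points
    origin = pts.min(axis=0)
    idx = np.round((pts - origin) / grid.spacing).astype(int)
    shape = idx.max(axis=0) + 1
    vol = np.zeros(shape, dtype=float)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = values
    affine = np.diag([grid.spacing] * 3 + [1.0])
    affine[:3, 3] = origin
    return vol, affine


def write_statmap_nifti(stat_map, path, sidecar: bool = True) -> None:
    """Stat map as a NIfTI volume (MNI mm) plus a JSON sidecar."""
    vol, affine = grid_to_volume(stat_map.grid, stat_map.values)
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    if stat_map.mask is not None:
        mvol, _ = grid_to_volume(stat_map.grid,
                                 stat_map.mask.astype(float))
        mask_path = str(path).replace(".nii", "_mask.nii")
        nib.save(nib.Nifti1Image(mvol, affine), mask_path)
    if sidecar:
        meta = {
            "kind": stat_map.kind,
            "df": stat_map.df,
            "band": stat_map.band,
            "window": stat_map.window,
            "threshold": stat_map.threshold,
            "spacing_mm": stat_map.grid.spacing,
            "n_points": int(stat_map.grid.n_points),
        }
        extras = {k: v for k, v in stat_map.extras.items()
                  if isinstance(v, (int, float, str, type(None)))}
        meta.update(extras)
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def write_peak_csv(peaks: pd.DataFrame, path) -> None:
    """Peak table in the (x, y, z, region, value) layout; region left blank."""
    out = peaks.copy()
    out.insert(3, "region", "")
    out.to_csv(path, index=False)


def write_tfmap(tf_map, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = tf_map.kind
        if tf_map.threshold is not None:
            f.attrs["threshold"] = tf_map.threshold
        f.create_dataset("values", data=tf_map.values)
        f.create_dataset("freq_hz", data=tf_map.freqs_hz)
        f.create_dataset("time_ms", data=tf_map.times_ms)
        if tf_map.mask is not None:
            f.create_dataset("mask", data=tf_map.mask)


def read_tfmap(path):
    from .virtual_electrode import TFMap

    with h5py.File(path, "r") as f:
        return TFMap(
            values=_require(f, "values")[()],
            freqs_hz=_require(f, "freq_hz")[()],
            times_ms=_require(f, "time_ms")[()],
            kind=str(f.attrs["kind"]),
            mask=f["mask"][()] if "mask" in f else None,
            threshold=float(f.attrs["threshold"])
            if "threshold" in f.attrs else None,
        )


def plot_tfmap(tf_map, path) -> None:
    """Heatmap with the significance mask outlined (dotted contour)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    extent = (tf_map.times_ms[0], tf_map.times_ms[-1],
              tf_map.freqs_hz[0], tf_map.freqs_hz[-1])
    im = ax.imshow(tf_map.values, aspect="auto", origin="lower",
                   extent=extent, cmap="RdBu_r")
    if tf_map.mask is not None and tf_map.mask.any():
        ax.contour(tf_map.times_ms, tf_map.freqs_hz,
                   tf_map.mask.astype(float), levels=[0.5],
                   colors="k", linestyles="dotted")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("frequency (Hz)")
    fig.colorbar(im, ax=ax, label=tf_map.kind)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------- config

class AnalysisConfig(BaseModel):
    """Validated analysis configuration (YAML-serializable)."""

    output_dir: str = "gammabeam_out"
    seed: int = 0
    n_per_group: dict[str, int] = Field(
        default_factory=lambda: {"TD": 8, "ASD": 8}
    )
    n_epochs: int = 60
    n_sensors: int = 64
    grid_spacing_mm: float = 5.0
    regularization: float = 0.05
    bands: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"lower": (3.0, 30.0), "gamma": (30.0, 80.0)}
    )
    passive_window_ms: tuple[float, float] = (-300.0, -100.0)
    active_windows_ms: tuple[tuple[float, float], ...] = (
        (50.0, 250.0), (250.0, 450.0), (450.0, 650.0)
    )
    n_permutations_group: int = 1000
    n_permutations_between: int = 300
    alpha_within: float = 0.05
    alpha_between: float = 0.001
    ve_sites: tuple[tuple[float, float, float], ...] = (
        (36.0, -86.0, 2.0), (-20.0, -92.0, 16.0), (32.0, -57.0, -3.0)
    )
    tf_freq_range: tuple[float, float] = (3.0, 100.0)
    tf_freq_step: float = 2.0
    per_emotion: bool = False

    @field_validator("grid_spacing_mm", "regularization")
    @classmethod
    def _non_negative(cls, v):
        if v < 0:
            raise ValueError("must be non-negative")
        return v

    @field_validator("n_epochs", "n_sensors")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v


def load_config(path) -> AnalysisConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return AnalysisConfig(**raw)


def dump_config(config: AnalysisConfig, path) -> None:
    """Write the resolved configuration next to the run outputs."""
    with open(path, "w") as f:
        yaml.safe_dump(json.loads(config.model_dump_json()), f,
                       sort_keys=False)
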