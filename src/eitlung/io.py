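"""Plain-text artifact formats and run configuration.

All formats are line-oriented text with documented headers; floats are
serialized with 17 significant digits so write-then-read is lossless to
<= 1 ulp.

* voltage frames: TSV with columns ``time_s`` then ``ch001..ch208`` plus a
  JSON sidecar (``<name>.meta.json``) holding frame rate, drive pattern and
  current amplitude;
* cohort: CSV ``id,age,sex,height_cm,weight_kg,chest_cm,predicted_fvc_L``;
* curves: TSV ``time_s<TAB>value``;
* image series: a directory of per-frame 32x32 CSV grids plus
  ``manifest.json`` (fps, lambda, prior, grid orientation);
* mesh: sectioned text file (nodes / elements / electrode arcs);
* run configuration: YAML, validated on load.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataQualityError, FormatError
from .forward import VoltageFrame, VoltageFrameSeries
from .mesh import Mesh
from .phantom import Subject
from .reconstruct import ImageSeries
from .waveform import ConductivityCurve, VolumeCurve

__all__ = [
    "write_frames", "read_frames",
    "write_cohort", "read_cohort",
    "write_curve", "read_curve", "read_conductivity_curve",
    "write_image_series", "read_image_series",
    "write_mesh", "read_mesh",
    "RunConfig",
]

FLOAT_FMT = "%.17g"


# ------------------------------------------------------------------ frames
def write_frames(path, series: VoltageFrameSeries, pattern_meta: dict | None = None):
    n_ch = series.values.shape[1]
    cols = ["time_s"] + [f"ch{i + 1:03d}" for i in range(n_ch)]
    df = pd.DataFrame(np.column_stack([series.times, series.values]), columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    meta = {"fps": series.fps, "n_channels": n_ch}
    meta.update(pattern_meta or {})
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_frames(path) -> VoltageFrameSeries:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "time_s" or len(header) < 2:
        raise FormatError(f"{path}: expected header 'time_s\\tch001...' (line 1)")
    n_ch = len(header) - 1
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    arr = df.to_numpy(dtype=float)
    for i, row in enumerate(arr):
        if row.size != n_ch + 1:
            raise FormatError(f"{path}: row {i + 2} has {row.size - 1} channels, expected {n_ch}")
    if np.isnan(arr).any():
        bad_cols = [header[j] for j in sorted(set(np.nonzero(np.isnan(arr))[1]))]
        raise DataQualityError(f"{path}: NaN values in columns {bad_cols}")
    meta_path = str(path) + ".meta.json"
    fps = None
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            fps = json.load(fh).get("fps")
    if fps is None:
        dt = np.median(np.diff(arr[:, 0])) if arr.shape[0] > 1 else 1.0
        fps = 1.0 / dt
    return VoltageFrameSeries(arr[:, 1:], arr[:, 0], float(fps))


# ------------------------------------------------------------------ cohort
COHORT_COLS = ["id", "age", "sex", "height_cm", "weight_kg", "chest_cm", "predicted_fvc_L"]


def write_cohort(path, cohort: list[Subject]):
    df = pd.DataFrame(
        [
            [s.id, s.age, s.sex, s.height, s.weight, s.chest, s.predicted_fvc]
            for s in cohort
        ],
        columns=COHORT_COLS,
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_cohort(path) -> list[Subject]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing cohort columns {missing}")
    subjects = []
    for i, row in df.iterrows():
        for c in ("height_cm", "weight_kg", "chest_cm", "predicted_fvc_L"):
            if not row[c] > 0:
                raise FormatError(f"{path}: row {i + 2}: {c} must be positive, got {row[c]}")
        subjects.append(
            Subject(
                id=str(row["id"]), age=float(row["age"]), sex=str(row["sex"]),
                height=float(row["height_cm"]), weight=float(row["weight_kg"]),
                chest=float(row["chest_cm"]), predicted_fvc=float(row["predicted_fvc_L"]),
            )
        )
    return subjects


# ------------------------------------------------------------------- curves
def write_curve(path, curve):
    vals = curve.volume if isinstance(curve, VolumeCurve) else curve.values
    df = pd.DataFrame({"time_s": curve.times, "value": vals})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_curve(path) -> VolumeCurve:
    df = _read_curve_df(path)
    return VolumeCurve(df["time_s"].to_numpy(), df["value"].to_numpy())


def read_conductivity_curve(path) -> ConductivityCurve:
    df = _read_curve_df(path)
    return ConductivityCurve(df["time_s"].to_numpy(), df["value"].to_numpy())


def _read_curve_df(path):
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != ["time_s", "value"]:
        raise FormatError(f"{path}: expected columns time_s, value (line 1)")
    return df


# ------------------------------------------------------------- image series
def write_image_series(dirpath, imgs: ImageSeries, extra_meta: dict | None = None):
    os.makedirs(dirpath, exist_ok=True)
    for i in range(imgs.n_frames):
        np.savetxt(
            os.path.join(dirpath, f"frame_{i:05d}.csv"),
            imgs.values[i], delimiter=",", fmt=FLOAT_FMT,
        )
    np.savetxt(os.path.join(dirpath, "inside_mask.csv"),
               imgs.inside_mask.astype(int), delimiter=",", fmt="%d")
    manifest = {
        "n_frames": imgs.n_frames,
        "fps": imgs.fps,
        "times": [float(t) for t in imgs.times],
        "grid": list(imgs.values.shape[1:]),
        "orientation": "caudal view: anterior = top row, subject left = viewer right",
    }
    manifest.update(extra_meta or {})
    with open(os.path.join(dirpath, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_image_series(dirpath) -> ImageSeries:
    mpath = os.path.join(dirpath, "manifest.json")
    if not os.path.exists(mpath):
        raise FormatError(f"{dirpath}: no manifest.json")
    with open(mpath) as fh:
        m = json.load(fh)
    frames = [
        np.loadtxt(os.path.join(dirpath, f"frame_{i:05d}.csv"), delimiter=",")
        for i in range(m["n_frames"])
    ]
    mask = np.loadtxt(os.path.join(dirpath, "inside_mask.csv"), delimiter=",").astype(bool)
    return ImageSeries(np.stack(frames), mask, m["fps"], np.array(m["times"]))


# --------------------------------------------------------------------- mesh
def write_mesh(path, mesh: Mesh):
    with open(path, "w") as fh:
        fh.write(f"# eitlung mesh v1 shape={mesh.shape} axis_ratio={mesh.axis_ratio!r}\n")
        fh.write(f"nodes {mesh.n_nodes}\n")
        for x, y in mesh.nodes:
            fh.write(f"{x:.17g} {y:.17g}\n")
        fh.write(f"elements {mesh.n_elements}\n")
        for a, b, c in mesh.elements:
            fh.write(f"{a} {b} {c}\n")
        fh.write(f"electrodes {len(mesh.electrode_arcs)}\n")
        for arc in mesh.electrode_arcs:
            fh.write(" ".join(map(str, arc)) + "\n")
        fh.write(f"boundary {len(mesh.boundary_nodes)}\n")
        fh.write(" ".join(map(str, mesh.boundary_nodes)) + "\n")


def read_mesh(path) -> Mesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("# eitlung mesh v1"):
        raise FormatError(f"{path}: not an eitlung mesh file (line 1)")
    head = dict(tok.split("=") for tok in lines[0].split()[4:])
    i = 1

    def expect(section):
        nonlocal i
        parts = lines[i].split()
        if parts[0] != section:
            raise FormatError(f"{path}: expected '{section}' at line {i + 1}")
        i += 1
        return int(parts[1])

    n = expect("nodes")
    nodes = np.array([[float(v) for v in lines[i + j].split()] for j in range(n)])
    i += n
    e = expect("elements")
    elements = np.array([[int(v) for v in lines[i + j].split()] for j in range(e)])
    i += e
    L = expect("electrodes")
    arcs = tuple(np.array([int(v) for v in lines[i + j].split()]) for j in range(L))
    i += L
    nb = expect("boundary")
    boundary = np.array([int(v) for v in lines[i].split()])
    if boundary.size != nb:
        raise FormatError(f"{path}: boundary node count mismatch at line {i + 1}")
    return Mesh(nodes, elements, arcs, boundary,
                shape=head.get("shape", "circle"),
                axis_ratio=float(head.get("axis_ratio", "1.0").strip("'")))


# ------------------------------------------------------------------- config
@dataclass
class RunConfig:
    """Validated pipeline configuration; round-trips losslessly via YAML."""

    seed: int = 0
    paradigm_kind: str = "forced"  # forced | guided
    inhale_depth: str = "full"
    exhale_speed: str = "fast"
    breathing_rate: float = 12.0
    duration: float = 10.0
    fps: float = 25.0
    mesh_shape: str = "circle"
    mesh_elements: int = 400
    axis_ratio: float = 1.0
    electrode_coverage: float = 0.5
    current_amplitude: float = 1e-3
    noise_snr_db: float = float("inf")
    lam: float | None = None  # None -> auto default
    prior: str = "noser"
    rho_min: float = 0.5
    amp_min_frac: float = 0.10
    act_frac: float = 0.25
    n_calibration_subjects: int = 4

    def validate(self):
        checks = [
            (self.paradigm_kind in ("forced", "guided"), "paradigm_kind must be forced|guided"),
            (0 < self.fps <= 50, "fps must be in (0, 50]"),
            (self.duration > 0, "duration must be positive"),
            (self.mesh_elements >= 64, "mesh_elements must be >= 64"),
            (0 < self.electrode_coverage <= 0.5, "electrode_coverage must be in (0, 0.5]"),
            (self.lam is None or self.lam > 0, "lambda must be positive"),
            (self.prior in ("identity", "noser"), "prior must be identity|noser"),
            (0 <= self.rho_min <= 1, "rho_min must be in [0, 1]"),
            (0 < self.amp_min_frac < 1, "amp_min_frac must be in (0, 1)"),
            (0 < self.act_frac < 1, "act_frac must be in (0, 1)"),
            (self.noise_snr_db > 0, "noise_snr_db must be positive (or inf)"),
            (self.current_amplitude > 0, "current_amplitude must be positive"),
            (self.n_calibration_subjects >= 4, "need >= 4 calibration subjects"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(msg)
        return self

    def to_yaml(self, path):
        d = asdict(self)
        d["noise_snr_db"] = "inf" if np.isinf(self.noise_snr_db) else self.noise_snr_db
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigurationError(f"{path}: config must be a YAML mapping")
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        if d.get("noise_snr_db") in ("inf", ".inf", None):
            d["noise_snr_db"] = float("inf")
        return cls(**d).validate()
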