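"""Registration accuracy evaluation: landmark target registration error (TRE).

Convention: landmarks are paired world points (mm) — a reference position in
the fixed frame and the manually/truth-identified corresponding position in
the moving frame.  The TRE of a fixed->moving transform is the Euclidean
distance between the transform-predicted moving-frame position of each fixed
landmark and its reference moving-frame position, i.e. the error is evaluated
on the fixed grid (the direction the registration was run in).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BSplineTransform, DisplacementField
from .errors import ContractError, ParseError

__all__ = ["LandmarkSet", "TREReport", "load_landmarks", "save_landmarks", "compute_tre"]

_COLUMNS = ["label", "fixed_x_mm", "fixed_y_mm", "fixed_z_mm",
            "moving_x_mm", "moving_y_mm", "moving_z_mm"]


@dataclass
class LandmarkSet:
    """Ordered pairs of fixed/moving world points (mm)."""

    fixed: np.ndarray   # (n, 3)
    moving: np.ndarray  # (n, 3)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.fixed = np.asarray(self.fixed, dtype=float)
        self.moving = np.asarray(self.moving, dtype=float)
        if self.fixed.ndim != 2 or self.fixed.shape[1] != 3:
            raise ContractError(f"fixed points must be (n,3), got {self.fixed.shape}")
        if self.fixed.shape != self.moving.shape:
            raise ContractError("fixed and moving landmark counts differ")
        if not (np.all(np.isfinite(self.fixed)) and np.all(np.isfinite(self.moving))):
            raise ContractError("landmark coordinates must be finite")
        if self.labels is None:
            self.labels = [f"L{i:03d}" for i in range(len(self.fixed))]
        elif len(self.labels) != len(self.fixed):
            raise ContractError("label count does not match landmark count")

    def __len__(self) -> int:
        return len(self.fixed)


@dataclass
class TREReport:
    """Per-landmark TRE distances (mm) with summary statistics."""

    distances: np.ndarray
    voxel_dimension: tuple[float, float, float]
    mean: float = field(init=False)
    sd: float = field(init=False)
    median: float = field(init=False)
    q25: float = field(init=False)
    q75: float = field(init=False)
    max: float = field(init=False)
    #: count of landmarks with TRE > max per-axis voxel dimension
    n_exceeding_voxel: int = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 1 or len(d) == 0 or np.any(d < 0):
            raise ContractError("distances must be a nonempty 1-D array of nonnegative values")
        self.distances = d
        self.mean = float(d.mean())
        self.sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
        self.median = float(np.median(d))
        self.q25 = float(np.percentile(d, 25))
        self.q75 = float(np.percentile(d, 75))
        self.max = float(d.max())
        self.n_exceeding_voxel = int((d > max(self.voxel_dimension)).sum())

    def as_dict(self) -> dict:
        return {
            "direction": "fixed-to-moving (errors evaluated on the fixed grid)",
            "n": int(len(self.distances)),
            "mean_mm": self.mean,
            "sd_mm": self.sd,
            "median_mm": self.median,
            "q25_mm": self.q25,
            "q75_mm": self.q75,
            "max_mm": self.max,
            "voxel_dimension_mm": list(self.voxel_dimension),
            "n_exceeding_voxel_dimension": self.n_exceeding_voxel,
        }


def load_landmarks(path: str | os.PathLike) -> LandmarkSet:
    """Read a landmark CSV with columns label, fixed_{x,y,z}_mm, moving_{x,y,z}_mm."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"could not parse landmark file {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"landmark file {path} contains no rows")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"landmark file {path} is missing columns {missing}")
    coords = np.column_stack(
        [pd.to_numeric(df[c], errors="coerce").to_numpy() for c in _COLUMNS[1:]]
    )
    bad = np.flatnonzero(~np.isfinite(coords).all(axis=1))
    if bad.size:
        raise ParseError(f"landmark file {path}: malformed row(s) at line(s) {(bad + 2).tolist()}")
    return LandmarkSet(
        fixed=coords[:, :3], moving=coords[:, 3:], labels=df["label"].astype(str).tolist()
    )


def save_landmarks(landmarks: LandmarkSet, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        np.hstack([landmarks.fixed, landmarks.moving]), columns=_COLUMNS[1:]
    )
    df.insert(0, "label", landmarks.labels)
    df.to_csv(path, index=False)


def compute_tre(
    landmarks: LandmarkSet,
    transform: DisplacementField | BSplineTransform,
    voxel_dimension: tuple[float, float, float],
) -> TREReport:
    """TRE of a fixed->moving transform against reference landmark pairs.

    Each fixed landmark is mapped by the transform; the TRE is the distance
    (mm) to the reference moving-frame landmark.
    """
    if isinstance(transform, (DisplacementField, BSplineTransform)):
        disp = transform.displacement_at(landmarks.fixed)
    else:
        raise ContractError(f"unsupported transform type {type(transform)!r}")
    if not np.all(np.isfinite(disp)):
        bad = landmarks.fixed[~np.isfinite(disp).all(axis=1)]
        raise ContractError(f"transform undefined at landmark point(s) {bad.tolist()}")
    predicted = landmarks.fixed + disp
    d = np.linalg.norm(predicted - landmarks.moving, axis=1)
    return TREReport(distances=d, voxel_dimension=tuple(float(v) for v in voxel_dimension))
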