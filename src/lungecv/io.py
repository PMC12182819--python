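"""NIfTI / CSV / YAML readers and writers, and the study manifest.

NIfTI-1 is the interchange format for volumes and maps (voxel size carried
by the affine); time series travel as CSV; the study layout is a YAML
manifest that round-trips losslessly through :class:`StudyManifest`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import ValidationError

__all__ = [
    "read_volume",
    "write_volume",
    "voxel_size_from_affine",
    "voxel_volume_ul",
    "PhaseEntry",
    "ConditionEntry",
    "SubjectEntry",
    "StudyManifest",
    "read_timeseries",
    "write_timeseries",
]


# --------------------------------------------------------------------------- #
# Volumes
# --------------------------------------------------------------------------- #

def write_volume(path, data: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0),
                 affine: np.ndarray | None = None) -> Path:
    """Write a volume as NIfTI-1; voxel size goes into a diagonal affine
    unless a full affine is given."""
    path = Path(path)
    if affine is None:
        affine = np.diag(list(voxel_size_mm[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))
    return path


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"volume not found: {path}")
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine)


def voxel_size_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    a = np.asarray(affine)[:3, :3]
    return tuple(float(np.linalg.norm(a[:, i])) for i in range(3))


def voxel_volume_ul(affine: np.ndarray) -> float:
    """Voxel volume in microliters (1 mm^3 = 1 uL)."""
    return float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))


def check_same_grid(affine_a, shape_a, affine_b, shape_b, what="volumes") -> None:
    if tuple(shape_a) != tuple(shape_b) or not np.allclose(affine_a, affine_b,
                                                           atol=1e-6):
        raise ValidationError(f"grid mismatch between paired {what}")


# --------------------------------------------------------------------------- #
# Time series
# --------------------------------------------------------------------------- #

def write_timeseries(path, **columns) -> Path:
    path = Path(path)
    pd.DataFrame(columns).to_csv(path, index=False)
    return path


def read_timeseries(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"time series not found: {path}")
    return pd.read_csv(path)


def write_json(path, obj) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# --------------------------------------------------------------------------- #
# Study manifest
# --------------------------------------------------------------------------- #

@dataclass
class PhaseEntry:
    """One acquired T1 series: file path + acquisition bookkeeping."""

    phase: str                     # native | gadolinium | ferumoxytol
    series: str                    # 4D NIfTI, last axis = saturation times
    order: int | None = None       # acquisition sequence index


@dataclass
class ConditionEntry:
    condition: str                 # naive | baseline | regurgitation | volume_loaded
    phases: list[PhaseEntry] = field(default_factory=list)
    pd_volume: str | None = None
    first_pass: str | None = None  # CSV: time_s, rv, lv
    flow: str | None = None        # CSV: time_s, flow_ml_s
    lv_volume: str | None = None   # CSV: time_s, volume_ml
    heart_rate_bpm: float | None = None
    truth: str | None = None       # JSON ground truth (phantom datasets)


@dataclass
class SubjectEntry:
    subject_id: str
    hematocrit: float
    conditions: list[ConditionEntry] = field(default_factory=list)


@dataclass
class StudyManifest:
    """Declares every file of a study: per-subject, per-condition,
    per-phase map identities plus acquisition metadata and seeds."""

    subjects: list[SubjectEntry] = field(default_factory=list)
    scenario: str = "naive"
    sat_times_ms: list[float] = field(default_factory=lambda: [104.0, 200.0, 374.0, 10000.0])
    averages: list[int] = field(default_factory=lambda: [8, 4, 4, 2])
    slice_indices: list[int] = field(default_factory=list)
    lung_mask: str | None = None
    body_mask: str | None = None
    blood_mask: str | None = None
    ap_axis: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyManifest":
        subjects = []
        for s in d.get("subjects", []):
            conds = []
            for c in s.get("conditions", []):
                phases = [PhaseEntry(**p) for p in c.get("phases", [])]
                conds.append(ConditionEntry(
                    **{**c, "phases": phases}
                ))
            subjects.append(SubjectEntry(
                **{**s, "conditions": conds}
            ))
        top = {k: v for k, v in d.items() if k != "subjects"}
        return cls(subjects=subjects, **top)

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path) -> "StudyManifest":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"manifest not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()))

    def validate_files(self, root: Path | None = None) -> None:
        """Check every referenced file exists and grids match per subject."""
        root = Path(root) if root is not None else Path(".")

        def _check(rel):
            if rel is not None and not (root / rel).exists():
                raise ValidationError(f"manifest references missing file: {rel}")

        for m in (self.lung_mask, self.body_mask, self.blood_mask):
            _check(m)
        for s in self.subjects:
            if s.hematocrit is None:
                raise ValidationError(f"subject {s.subject_id}: missing hematocrit")
            for c in s.conditions:
                for p in c.phases:
                    _check(p.series)
                for f in (c.pd_volume, c.first_pass, c.flow, c.lv_volume, c.truth):
                    _check(f)
                affs = []
                for p in c.phases:
                    _, aff = read_volume(root / p.series)
                    affs.append((p.series, aff))
                for (na, aa), (nb, ab) in zip(affs[:-1], affs[1:]):
                    if not np.allclose(aa, ab, atol=1e-6):
                        raise ValidationError(
                            f"grid mismatch between {na} and {nb}"
                        )
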