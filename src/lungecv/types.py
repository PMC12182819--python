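"""Shared domain containers for the dual-contrast lung water pipeline.

All internal quantities follow one unit convention: T1 in ms, R1 and dR1 in
1/ms, concentrations in mmol/L, relaxivities in L/mmol/s, volumes in mL
(lung volumes reported in L where noted), fractions stored as fractions and
reported as percent only at the formatting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LungECVError",
    "ValidationError",
    "CompartmentMap",
    "ContrastPhase",
    "PhantomTruth",
    "SaturationRecoverySeries",
    "T1Map",
    "DeltaR1",
    "ECVResult",
    "RegionalECV",
    "LWDMap",
    "LungWaterResult",
    "FlowCurve",
    "LVVolumeCurve",
    "FirstPassCurves",
]


class LungECVError(Exception):
    """Base class for pipeline errors."""


class ValidationError(LungECVError):
    """An input violated a documented contract."""


# --------------------------------------------------------------------------- #
# Phantom ground truth
# --------------------------------------------------------------------------- #

@dataclass
class CompartmentMap:
    """Voxelwise four-compartment decomposition of a digital thorax.

    ``f_air`` is the MR-invisible volume fraction: alveolar air inside the
    lungs, non-water solids in body tissue (so body voxels carry the 70%
    musculoskeletal water density the lung-water normalization assumes).
    The remaining three compartments are water: intracellular (``f_ic``),
    extravascular extracellular / interstitial (``f_ev``) and blood plasma
    (``f_pl``).  In blood-pool voxels the intracellular water is the red-cell
    water, identified with the hematocrit, so a blood voxel has
    ``f_ic = hct`` and ``f_pl = 1 - hct``.
    """

    voxel_size_mm: tuple[float, float, float]
    f_air: np.ndarray
    f_ic: np.ndarray
    f_ev: np.ndarray
    f_pl: np.ndarray
    lung_mask: np.ndarray
    body_mask: np.ndarray
    blood_mask: np.ndarray
    hematocrit: float
    ap_axis: int = 1  # anteroposterior axis; posterior = increasing index

    @property
    def shape(self) -> tuple[int, ...]:
        return self.f_air.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def water(self) -> np.ndarray:
        """Total water (non-air) volume fraction per voxel."""
        return self.f_ic + self.f_ev + self.f_pl

    def validate(self, atol: float = 1e-9) -> None:
        total = self.f_air + self.water
        if not np.allclose(total, 1.0, atol=atol):
            worst = float(np.abs(total - 1.0).max())
            raise ValidationError(
                f"compartment fractions do not sum to 1 (max |err| = {worst:.3g})"
            )
        for name in ("f_air", "f_ic", "f_ev", "f_pl"):
            arr = getattr(self, name)
            if arr.min() < -atol or arr.max() > 1 + atol:
                raise ValidationError(f"{name} outside [0, 1]")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValidationError(f"hematocrit {self.hematocrit} outside (0, 1)")
        if np.any(self.f_air[self.blood_mask] > atol):
            raise ValidationError("air fraction nonzero inside the blood pool")
        for a, b in (("lung_mask", "body_mask"), ("lung_mask", "blood_mask"),
                     ("body_mask", "blood_mask")):
            if np.any(getattr(self, a) & getattr(self, b)):
                raise ValidationError(f"{a} and {b} overlap")


@dataclass
class ContrastPhase:
    """Contrast-agent state of one imaging phase.

    The gadolinium chelate equilibrates across the whole extracellular space
    (plasma + interstitium); ferumoxytol stays intravascular, so it never
    contributes relaxation to the extravascular-extracellular compartment.
    ``gadolinium_mmol_l`` at the ferumoxytol phase models residual chelate
    (an optional confounder, default zero).
    """

    label: str  # native | gadolinium | ferumoxytol
    gadolinium_mmol_l: float = 0.0
    ferumoxytol_mmol_l: float = 0.0
    r1_gadolinium: float = 4.5   # L/mmol/s
    r1_ferumoxytol: float = 15.0  # L/mmol/s

    def __post_init__(self) -> None:
        for name in ("gadolinium_mmol_l", "ferumoxytol_mmol_l",
                     "r1_gadolinium", "r1_ferumoxytol"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")


@dataclass
class PhantomTruth:
    """Ground-truth quantities exported with every phantom.

    Fractions are air-excluded: 100% of the measured volume fraction is
    ascribed to the sum of ECV and intracellular volume, mirroring how
    T1-based ECV is insensitive to air.
    """

    ecv: float
    pvf: float
    ecv_extravascular: float
    lung_water_density: float
    lung_volume_l: float
    lung_water_volume_ml: float
    ev_lung_water_volume_ml: float
    hematocrit: float
    ptt_s: float | None = None
    sv_aorta_ml: float | None = None
    sv_lv_ml: float | None = None
    regurgitant_fraction: float | None = None
    heart_rate_bpm: float | None = None
    cardiac_output_l_min: float | None = None

    @classmethod
    def from_map(cls, cmap: CompartmentMap, **hemo) -> "PhantomTruth":
        m = cmap.lung_mask
        water = cmap.water[m]
        ecv = float(np.mean((cmap.f_ev[m] + cmap.f_pl[m]) / water))
        pvf = float(np.mean(cmap.f_pl[m] / water))
        lwd = float(np.mean(water))
        vol_l = float(m.sum()) * cmap.voxel_volume_mm3 * 1e-6
        lwv = lwd * vol_l * 1e3
        return cls(
            ecv=ecv,
            pvf=pvf,
            ecv_extravascular=ecv - pvf,
            lung_water_density=lwd,
            lung_volume_l=vol_l,
            lung_water_volume_ml=lwv,
            ev_lung_water_volume_ml=(ecv - pvf) * lwv,
            hematocrit=cmap.hematocrit,
            **hemo,
        )


# --------------------------------------------------------------------------- #
# Relaxometry containers
# --------------------------------------------------------------------------- #

@dataclass
class SaturationRecoverySeries:
    """Saturation-time-indexed image stack for T1 fitting.

    ``frames`` has shape ``(n_sat_times,) + grid_shape``; every frame shares
    one voxel grid.  ``averages`` records how many signal averages each
    saturation time received (used as fit weights).
    """

    sat_times_ms: np.ndarray
    averages: np.ndarray
    frames: np.ndarray
    slice_indices: tuple[int, ...] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sat_times_ms = np.asarray(self.sat_times_ms, dtype=float)
        self.averages = np.asarray(self.averages, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        n = self.sat_times_ms.size
        if self.averages.size != n or self.frames.shape[0] != n:
            raise ValidationError("sat_times, averages and frames are misaligned")
        if np.unique(self.sat_times_ms).size < 2:
            raise ValidationError("need at least two distinct saturation times")
        if np.any(self.sat_times_ms <= 0):
            raise ValidationError("saturation times must be positive")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.frames.shape[1:]


@dataclass
class T1Map:
    """Per-voxel T1 with fit diagnostics; invalid voxels carry NaN."""

    t1_ms: np.ndarray
    a: np.ndarray
    b: np.ndarray
    resid_norm: np.ndarray
    valid: np.ndarray
    window_ms: tuple[float, float] = (50.0, 3000.0)
    model: str = "3param"


@dataclass
class DeltaR1:
    """Change in longitudinal relaxation rate, 1/T1_contrast - 1/T1_native."""

    value: float  # 1/ms
    t1_contrast_ms: float
    t1_native_ms: float
    phase_contrast: str = "contrast"
    phase_native: str = "native"

    def __float__(self) -> float:
        return float(self.value)


# --------------------------------------------------------------------------- #
# Compartment results
# --------------------------------------------------------------------------- #

@dataclass
class ECVResult:
    """Dual-agent compartment fractions for one ROI and condition.

    Invariant: ``ecv_extravascular == ecv - pvf`` exactly.  Fractions outside
    the soft physiological window [0, 1.2] are flagged, never clipped.
    """

    condition: str
    hematocrit: float
    ecv: float | None = None
    pvf: float | None = None
    ecv_extravascular: float | None = None
    dr1_lung_gadolinium: float | None = None
    dr1_blood_gadolinium: float | None = None
    dr1_lung_ferumoxytol: float | None = None
    dr1_blood_ferumoxytol: float | None = None
    flags: list[str] = field(default_factory=list)

    def check(self) -> None:
        if self.ecv is not None and self.pvf is not None:
            ev = self.ecv - self.pvf
            if self.ecv_extravascular is None:
                self.ecv_extravascular = ev
            elif self.ecv_extravascular != ev:
                raise ValidationError("ecv_extravascular must equal ecv - pvf")
        for name in ("ecv", "pvf", "ecv_extravascular"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.2):
                flag = f"{name}_outside_physiological_window"
                if flag not in self.flags:
                    self.flags.append(flag)


@dataclass
class RegionalECV:
    """Anterior / mid / posterior ECVResult triple along the AP axis."""

    anterior: ECVResult
    mid: ECVResult
    posterior: ECVResult
    boundaries: tuple[int, int, int, int]  # bbox edges: [a0, a1, a2, a3)

    def as_dict(self) -> dict[str, ECVResult]:
        return {"anterior": self.anterior, "mid": self.mid,
                "posterior": self.posterior}


# --------------------------------------------------------------------------- #
# Lung water containers
# --------------------------------------------------------------------------- #

@dataclass
class LWDMap:
    """Lung water density map: water volume per voxel volume (air included)."""

    density: np.ndarray
    lung_mask: np.ndarray
    body_median: float
    shading_order: int | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class LungWaterResult:
    global_density: float          # fraction
    lung_volume_l: float
    lung_water_volume_ml: float
    ev_lung_water_volume_ml: float | None = None

    def check(self) -> None:
        expected = self.global_density * self.lung_volume_l * 1e3
        if not np.isclose(self.lung_water_volume_ml, expected, rtol=1e-12):
            raise ValidationError("lung water volume != density * volume")
        if (self.ev_lung_water_volume_ml is not None
                and self.ev_lung_water_volume_ml > self.lung_water_volume_ml + 1e-9):
            raise ValidationError("extravascular volume exceeds lung water volume")


# --------------------------------------------------------------------------- #
# Time series
# --------------------------------------------------------------------------- #

@dataclass
class FlowCurve:
    """Through-plane flow waveform with beat boundaries (R-wave times)."""

    time_s: np.ndarray
    flow_ml_s: np.ndarray
    heart_rate_bpm: float | None = None
    beat_times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.flow_ml_s = np.asarray(self.flow_ml_s, dtype=float)
        if self.time_s.shape != self.flow_ml_s.shape:
            raise ValidationError("time and flow lengths differ")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValidationError("time grid must be strictly increasing")


@dataclass
class LVVolumeCurve:
    time_s: np.ndarray
    volume_ml: np.ndarray


@dataclass
class FirstPassCurves:
    """RV and LV time-intensity curves of a first-pass bolus."""

    time_s: np.ndarray
    rv: np.ndarray
    lv: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.rv = np.asarray(self.rv, dtype=float)
        self.lv = np.asarray(self.lv, dtype=float)
        if not (self.time_s.shape == self.rv.shape == self.lv.shape):
            raise ValidationError("first-pass curves must share the time grid")

    @property
    def frame_interval_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))
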