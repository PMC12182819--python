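"""Dual-contrast compartment fractions: ECV, plasma volume fraction, and
their difference, plus the study's phase pairing and the anteroposterior
regional breakdown.

The extracellular volume fraction from ROI-mean T1s is

    ECV = (1 - Hct) * dR1_lung / dR1_blood,    dR1 = 1/T1_contrast - 1/T1_native

With the purely intravascular agent (ferumoxytol) the same ratio measures
only the plasma compartment; we call it the plasma volume fraction (PVF).
The interstitial (extravascular, non-blood) extracellular fraction is the
subtraction ECV_extravascular = ECV - PVF, an exact identity on every
emitted result.  All fractions are air-excluded: they describe shares of the
non-air tissue water, since T1 mapping is insensitive to air.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ECVResult, LungECVError, RegionalECV, ValidationError

__all__ = [
    "compute_ecv",
    "compute_pvf",
    "compute_ecv_extravascular",
    "ecv_result_from_t1",
    "pair_phases",
    "PhasePair",
    "regional_sections",
    "UninterpretableContrastError",
    "MissingPhaseError",
]

DR1_TOL = 1e-12  # 1/ms; below this the contrast change is uninterpretable


class UninterpretableContrastError(LungECVError):
    """Blood dR1 is (near) zero: no usable contrast change."""


class MissingPhaseError(LungECVError):
    """A study manifest lacks a required phase."""


def _as_float(x) -> float:
    return float(x)


def compute_ecv(dr1_lung, dr1_blood, hematocrit: float,
                flags: list[str] | None = None) -> float:
    """Extracellular volume fraction from a dR1 pair and hematocrit.

    Accepts floats or DeltaR1 objects.  Negative dR1 inputs are physically
    suspect (post-contrast T1 longer than native) and are recorded in
    ``flags`` when a list is supplied; the value is still returned, never
    clipped.
    """
    if not 0.0 < hematocrit < 1.0:
        raise ValidationError(f"hematocrit {hematocrit} outside (0, 1)")
    lung = _as_float(dr1_lung)
    blood = _as_float(dr1_blood)
    if abs(blood) < DR1_TOL:
        raise UninterpretableContrastError(
            f"blood dR1 = {blood:.3g} 1/ms is below tolerance; the contrast "
            "change is uninterpretable"
        )
    if flags is not None and (lung < 0 or blood < 0):
        flags.append("negative_delta_r1")
    return (1.0 - hematocrit) * lung / blood


def compute_pvf(dr1_lung_ferumoxytol, dr1_blood_ferumoxytol,
                hematocrit: float, flags: list[str] | None = None) -> float:
    """Plasma volume fraction: the ECV formula with ferumoxytol dR1 measured
    against the native (pre-gadolinium) R1."""
    return compute_ecv(dr1_lung_ferumoxytol, dr1_blood_ferumoxytol,
                       hematocrit, flags=flags)


def compute_ecv_extravascular(ecv: float, pvf: float,
                              flags: list[str] | None = None) -> float:
    """ECV_extravascular = ECV - plasma volume fraction (exact subtraction).

    A negative result is flagged, not truncated, so group statistics on the
    emitted values remain valid.
    """
    if not (np.isfinite(ecv) and np.isfinite(pvf)):
        raise ValidationError("ECV and PVF must be finite")
    ev = ecv - pvf
    if flags is not None and ev < 0:
        flags.append("negative_ecv_extravascular")
    return ev


def ecv_result_from_t1(
    condition: str,
    hematocrit: float,
    t1_lung_native_ms: float,
    t1_blood_native_ms: float,
    t1_lung_gadolinium_ms: float | None = None,
    t1_blood_gadolinium_ms: float | None = None,
    t1_lung_ferumoxytol_ms: float | None = None,
    t1_blood_ferumoxytol_ms: float | None = None,
) -> ECVResult:
    """Assemble a full ECVResult from ROI T1 means of up to three phases.

    Both contrast agents are referenced to the same native T1 pair (the
    ferumoxytol dR1 uses the pre-gadolinium native R1, not a re-baselined
    post-gadolinium one).
    """
    from .relaxometry import delta_r1

    flags: list[str] = []
    res = ECVResult(condition=condition, hematocrit=hematocrit, flags=flags)
    if t1_lung_gadolinium_ms is not None:
        dl = delta_r1(t1_lung_gadolinium_ms, t1_lung_native_ms)
        db = delta_r1(t1_blood_gadolinium_ms, t1_blood_native_ms)
        res.dr1_lung_gadolinium = float(dl)
        res.dr1_blood_gadolinium = float(db)
        res.ecv = compute_ecv(dl, db, hematocrit, flags=flags)
    if t1_lung_ferumoxytol_ms is not None:
        dl = delta_r1(t1_lung_ferumoxytol_ms, t1_lung_native_ms)
        db = delta_r1(t1_blood_ferumoxytol_ms, t1_blood_native_ms)
        res.dr1_lung_ferumoxytol = float(dl)
        res.dr1_blood_ferumoxytol = float(db)
        res.pvf = compute_pvf(dl, db, hematocrit, flags=flags)
    if res.ecv is not None and res.pvf is not None:
        res.ecv_extravascular = compute_ecv_extravascular(res.ecv, res.pvf,
                                                          flags=flags)
    res.check()
    return res


# --------------------------------------------------------------------------- #
# Phase pairing
# --------------------------------------------------------------------------- #

@dataclass
class PhasePair:
    """One (native, contrast) map pairing resolved from a study layout."""

    condition: str
    agent: str                      # gadolinium | ferumoxytol
    native: dict
    contrast: dict
    order_variant: bool = False     # ferumoxytol administered before gadolinium


def pair_phases(phases: list[dict]) -> list[PhasePair]:
    """Resolve the study's native/contrast pairings from a phase manifest.

    ``phases`` is a list of records with at least ``condition`` (naive |
    baseline | regurgitation | volume_loaded) and ``phase`` (native |
    gadolinium | ferumoxytol); an optional ``order`` index records the
    acquisition sequence.  Pairing rules:

    * baseline / regurgitation maps are paired separately, each condition
      using its own native map (consistent physiology);
    * volume_loaded uses the post-infusion native map (the ``volume_loaded``
      native record);
    * naive uses its single native map for both agents;
    * a naive layout where ferumoxytol precedes gadolinium is still
      resolvable but its gadolinium pair is labelled ``order_variant``.
    """
    by_cond: dict[str, dict[str, dict]] = {}
    for rec in phases:
        try:
            cond, ph = rec["condition"], rec["phase"]
        except KeyError as exc:
            raise ValidationError(f"phase record missing key {exc}") from None
        if ph in by_cond.setdefault(cond, {}):
            raise ValidationError(f"duplicate phase {ph!r} for {cond!r}")
        by_cond[cond][ph] = rec

    pairs: list[PhasePair] = []
    for cond in sorted(by_cond):
        recs = by_cond[cond]
        if "native" not in recs:
            raise MissingPhaseError(
                f"condition {cond!r} is missing its native T1 map"
            )
        native = recs["native"]
        for agent in ("gadolinium", "ferumoxytol"):
            if agent not in recs:
                continue
            contrast = recs[agent]
            order_variant = False
            if agent == "gadolinium" and "ferumoxytol" in recs:
                o_gad = recs["gadolinium"].get("order")
                o_fex = recs["ferumoxytol"].get("order")
                if o_gad is not None and o_fex is not None and o_fex < o_gad:
                    order_variant = True
            pairs.append(PhasePair(condition=cond, agent=agent,
                                   native=native, contrast=contrast,
                                   order_variant=order_variant))
    if not pairs:
        raise MissingPhaseError("no contrast phases found in the manifest")
    return pairs


# --------------------------------------------------------------------------- #
# Regional sections
# --------------------------------------------------------------------------- #

def regional_sections(
    lung_mask: np.ndarray, ap_axis: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int, int, int]]:
    """Split the lungs into anterior / mid / posterior thirds.

    The lung-mask bounding-box extent along the anteroposterior axis is
    divided into three equal parts (posterior = increasing index); when the
    extent is not divisible by three, the remainder voxels go to the
    posterior-most eligible sections.  Each sub-mask is the intersection of
    the lung mask with its third.

    Returns (anterior, mid, posterior, boundaries) where ``boundaries`` are
    the AP index edges [a0, a1, a2, a3).
    """
    if not np.any(lung_mask):
        raise ValidationError("lung mask is empty")
    ap = np.indices(lung_mask.shape)[ap_axis]
    idx = ap[lung_mask]
    lo, hi = int(idx.min()), int(idx.max())
    extent = hi - lo + 1
    if extent < 3:
        raise ValidationError(
            f"anteroposterior extent {extent} voxels is too small to split"
        )
    base, rem = divmod(extent, 3)
    sizes = [base, base + (1 if rem == 2 else 0), base + (1 if rem >= 1 else 0)]
    a0 = lo
    a1 = a0 + sizes[0]
    a2 = a1 + sizes[1]
    a3 = a2 + sizes[2]
    anterior = lung_mask & (ap >= a0) & (ap < a1)
    mid = lung_mask & (ap >= a1) & (ap < a2)
    posterior = lung_mask & (ap >= a2) & (ap < a3)
    return anterior, mid, posterior, (a0, a1, a2, a3)


def regional_ecv_result(results: dict[str, ECVResult],
                        boundaries: tuple[int, int, int, int]) -> RegionalECV:
    return RegionalECV(anterior=results["anterior"], mid=results["mid"],
                       posterior=results["posterior"], boundaries=boundaries)
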