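"""File-based orchestration: phantom dataset writer and end-to-end runner.

``write_phantom_dataset`` forward-simulates a scenario cohort to NIfTI/CSV
files plus a YAML manifest with exported ground truth;  ``run_pipeline``
consumes any manifest of that layout (simulated or acquired) and produces
the full results bundle: per-subject dual-agent compartment fractions, lung
water volumes, hemodynamics, and the group summary statistics.  Results are
deterministic given the manifest and its seeds.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import hemodynamics as hemo
from . import lung_water as lw
from .compartments import ecv_result_from_t1, pair_phases, regional_sections
from .io import (
    ConditionEntry,
    PhaseEntry,
    StudyManifest,
    SubjectEntry,
    read_timeseries,
    read_volume,
    write_json,
    write_timeseries,
    write_volume,
)
from .phantom import (
    AcquisitionConfig,
    build_phantom,
    contrast_phases,
    default_shading_coeffs,
    scenario_params,
    simulate_first_pass,
    simulate_flow,
    simulate_proton_density,
    simulate_sasha_series,
    simulate_t1_volume,
)
from .relaxometry import fit_t1, roi_t1
from .stats_report import paired_t, summary_table
from .types import FirstPassCurves, FlowCurve, LVVolumeCurve, LungECVError, ValidationError

logger = logging.getLogger("lungecv")

__all__ = ["write_phantom_dataset", "run_pipeline"]


# --------------------------------------------------------------------------- #
# Dataset writer
# --------------------------------------------------------------------------- #

def write_phantom_dataset(
    out_dir,
    scenario: str = "naive",
    n_subjects: int = 1,
    seed: int = 0,
    acq: AcquisitionConfig | None = None,
    pd_noise: float = 0.0,
    shading: bool = True,
    jitter: bool = True,
    params=None,
) -> Path:
    """Simulate a cohort to disk; returns the manifest path.

    Layout: masks at the root (shared geometry), one directory per subject
    and condition holding the three SASHA series (4D NIfTI, last axis =
    saturation time), the proton-density volume, first-pass and flow CSVs,
    and a ground-truth JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acq = acq if acq is not None else AcquisitionConfig()
    acq.validate()
    params = params if params is not None else scenario_params(scenario)
    phases = contrast_phases()
    rng = np.random.default_rng(seed)

    manifest = StudyManifest(scenario=params.name, seed=seed)
    ts, av = acq.sampling()
    manifest.sat_times_ms = [float(x) for x in ts]
    manifest.averages = [int(x) for x in av]

    wrote_masks = False
    for s in range(n_subjects):
        subj_seed = seed + 7919 * (s + 1)
        entry = SubjectEntry(subject_id=f"subject_{s:02d}", hematocrit=0.0)
        for condition in params.conditions:
            cmap, truth = build_phantom(scenario, params=params,
                                        seed=subj_seed, condition=condition,
                                        jitter=jitter)
            entry.hematocrit = cmap.hematocrit
            vox = cmap.voxel_size_mm
            nz = cmap.shape[2]
            start = (nz - acq.n_slices) // 2
            slices = list(range(start, start + acq.n_slices))
            manifest.slice_indices = slices
            manifest.ap_axis = cmap.ap_axis

            if not wrote_masks:
                for name, m in (("lung_mask", cmap.lung_mask),
                                ("body_mask", cmap.body_mask),
                                ("blood_mask", cmap.blood_mask)):
                    write_volume(out / f"{name}.nii", m.astype(np.float64), vox)
                    setattr(manifest, name, f"{name}.nii")
                wrote_masks = True

            cdir = out / entry.subject_id / condition
            cdir.mkdir(parents=True, exist_ok=True)
            cond_entry = ConditionEntry(condition=condition)

            for order, (name, phase) in enumerate(phases.items()):
                t1_vol = simulate_t1_volume(cmap, phase)
                series = simulate_sasha_series(
                    t1_vol, acq, proton_density=cmap.water,
                    slices=tuple(slices),
                    seed=int(rng.integers(0, 2 ** 31 - 1)),
                )
                # frames (n_ts, nx, ny, nsl) -> (nx, ny, nsl, n_ts)
                data = np.moveaxis(series.frames, 0, -1)
                rel = f"{entry.subject_id}/{condition}/t1_series_{name}.nii"
                write_volume(out / rel, data, vox)
                cond_entry.phases.append(PhaseEntry(phase=name, series=rel,
                                                    order=order))

            coeffs = (default_shading_coeffs(seed=int(rng.integers(0, 2 ** 31 - 1)))
                      if shading else None)
            pd_vol = simulate_proton_density(
                cmap, shading_coeffs=coeffs, noise_level=pd_noise,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            rel = f"{entry.subject_id}/{condition}/pd.nii"
            write_volume(out / rel, pd_vol, vox)
            cond_entry.pd_volume = rel

            curves = simulate_first_pass(ptt_true_s=truth.ptt_s,
                                         seed=int(rng.integers(0, 2 ** 31 - 1)))
            rel = f"{entry.subject_id}/{condition}/first_pass.csv"
            write_timeseries(out / rel, time_s=curves.time_s,
                             rv=curves.rv, lv=curves.lv)
            cond_entry.first_pass = rel

            flow, lv_curve = simulate_flow(
                stroke_volume_ml=truth.sv_aorta_ml,
                heart_rate_bpm=truth.heart_rate_bpm,
                regurgitant_fraction=truth.regurgitant_fraction,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            rel = f"{entry.subject_id}/{condition}/flow.csv"
            write_timeseries(out / rel, time_s=flow.time_s,
                             flow_ml_s=flow.flow_ml_s)
            cond_entry.flow = rel
            rel = f"{entry.subject_id}/{condition}/lv_volume.csv"
            write_timeseries(out / rel, time_s=lv_curve.time_s,
                             volume_ml=lv_curve.volume_ml)
            cond_entry.lv_volume = rel
            cond_entry.heart_rate_bpm = truth.heart_rate_bpm

            rel = f"{entry.subject_id}/{condition}/truth.json"
            write_json(out / rel, asdict(truth))
            cond_entry.truth = rel

            entry.conditions.append(cond_entry)
        manifest.subjects.append(entry)

    return manifest.save(out / "manifest.yaml")


# --------------------------------------------------------------------------- #
# Runner
# --------------------------------------------------------------------------- #

def _stage(subject: str, stage: str):
    logger.info("subject=%s stage=%s (lungecv %s)", subject, stage, __version__)


def run_pipeline(
    manifest_path,
    regional: bool = False,
    model: str = "3param",
    shading_order: int = 2,
    out_dir=None,
) -> dict:
    """Run the full analysis described by a study manifest.

    Returns a bundle with per-subject results (``table``: one row per
    subject x condition), the group mean +/- SD ``summary``, and paired
    ``stats`` when the manifest holds paired conditions.  Any stage error
    is re-raised annotated with the subject id and stage name.
    """
    manifest_path = Path(manifest_path)
    manifest = StudyManifest.load(manifest_path)
    root = manifest_path.parent
    manifest.validate_files(root)

    lung3d, _ = read_volume(root / manifest.lung_mask)
    body3d, _ = read_volume(root / manifest.body_mask)
    blood3d, aff = read_volume(root / manifest.blood_mask)
    lung3d, body3d, blood3d = (m > 0.5 for m in (lung3d, body3d, blood3d))
    voxel_mm = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    slices = tuple(manifest.slice_indices)

    def _sub(m):
        return np.take(m, slices, axis=2)

    rois = {"lung": _sub(lung3d), "blood": _sub(blood3d)}
    sections3d = {}
    if regional:
        ant, mid, post, _ = regional_sections(lung3d, manifest.ap_axis)
        sections3d = {"anterior": ant, "mid": mid, "posterior": post}
        rois.update({k: _sub(m) for k, m in sections3d.items()})
    fit_mask = np.zeros_like(rois["lung"])
    for m in rois.values():
        fit_mask |= m

    body_ref = lw.body_reference_mask(body3d, lung3d, blood3d)

    rows = []
    for subj in manifest.subjects:
        for cond in subj.conditions:
            try:
                row = _run_condition(
                    root, manifest, subj, cond, rois, fit_mask, lung3d,
                    body_ref, voxel_mm, model, shading_order, regional,
                )
            except LungECVError as exc:
                raise type(exc)(
                    f"subject={subj.subject_id} condition={cond.condition}: {exc}"
                ) from exc
            rows.append(row)
    table = pd.DataFrame(rows)

    groups = {
        cond: {
            m: table.loc[table["condition"] == cond, m].to_numpy()
            for m in ("ecv", "pvf", "ecv_ev")
            if m in table
        }
        for cond in table["condition"].unique()
    }
    summary = summary_table(groups, percent_metrics=("ecv", "pvf", "ecv_ev"))

    stats = {}
    conds = set(table["condition"])
    if {"baseline", "regurgitation"} <= conds:
        a = table[table["condition"] == "baseline"].sort_values("subject")
        b = table[table["condition"] == "regurgitation"].sort_values("subject")
        for metric in ("ecv", "pvf", "ecv_ev"):
            t, p = paired_t(a[metric].to_numpy(), b[metric].to_numpy())
            stats[f"paired_{metric}"] = {"t": t, "p": p}

    bundle = {
        "manifest": manifest_path.name,
        "version": __version__,
        "table": table,
        "summary": summary,
        "stats": stats,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.csv", index=False)
        summary.to_csv(out / "summary.csv")
        write_json(out / "stats.json", stats)
    return bundle


def _run_condition(root, manifest, subj, cond, rois, fit_mask, lung3d,
                   body_ref, voxel_mm, model, shading_order, regional):
    _stage(subj.subject_id, f"t1-fit:{cond.condition}")
    ts = np.asarray(manifest.sat_times_ms, float)
    av = np.asarray(manifest.averages, float)

    t1_by_phase: dict[str, dict[str, float]] = {}
    records = []
    for ph in cond.phases:
        data, _ = read_volume(root / ph.series)
        frames = np.moveaxis(data, -1, 0)
        from .types import SaturationRecoverySeries

        series = SaturationRecoverySeries(sat_times_ms=ts, averages=av,
                                          frames=frames)
        t1_map = fit_t1(series, mask=fit_mask, model=model)
        t1_by_phase[ph.phase] = {k: roi_t1(t1_map, m) for k, m in rois.items()}
        records.append({"condition": cond.condition, "phase": ph.phase,
                        "order": ph.order})

    pairs = pair_phases(records)

    def _result(lung_key):
        kw = {}
        for pr in pairs:
            agent = pr.agent
            kw[f"t1_lung_{agent}_ms"] = t1_by_phase[agent][lung_key]
            kw[f"t1_blood_{agent}_ms"] = t1_by_phase[agent]["blood"]
        return ecv_result_from_t1(
            condition=cond.condition,
            hematocrit=subj.hematocrit,
            t1_lung_native_ms=t1_by_phase["native"][lung_key],
            t1_blood_native_ms=t1_by_phase["native"]["blood"],
            **kw,
        )

    res = _result("lung")
    row = {
        "subject": subj.subject_id,
        "condition": cond.condition,
        "hct": subj.hematocrit,
        "ecv": res.ecv,
        "pvf": res.pvf,
        "ecv_ev": res.ecv_extravascular,
        "flags": ";".join(res.flags),
    }
    if regional:
        for region in ("anterior", "mid", "posterior"):
            r = _result(region)
            row[f"ecv_{region}"] = r.ecv
            row[f"pvf_{region}"] = r.pvf
            row[f"ecv_ev_{region}"] = r.ecv_extravascular

    if cond.pd_volume:
        _stage(subj.subject_id, f"lung-water:{cond.condition}")
        pd_vol, _ = read_volume(root / cond.pd_volume)
        corrected, _ = lw.shading_correction(pd_vol, body_ref,
                                             order=shading_order)
        _, lw_res = lw.summarize(
            corrected, lung3d, body_ref, voxel_mm,
            ecv_extravascular=res.ecv_extravascular,
            shading_order=shading_order,
        )
        row.update({
            "lwd": lw_res.global_density,
            "lung_volume_l": lw_res.lung_volume_l,
            "lwv_ml": lw_res.lung_water_volume_ml,
            "ev_lwv_ml": lw_res.ev_lung_water_volume_ml,
        })

    if cond.flow:
        _stage(subj.subject_id, f"hemodynamics:{cond.condition}")
        df = read_timeseries(root / cond.flow)
        flow = FlowCurve(time_s=df["time_s"].to_numpy(),
                         flow_ml_s=df["flow_ml_s"].to_numpy(),
                         heart_rate_bpm=cond.heart_rate_bpm)
        sv = hemo.stroke_volume(flow)
        row["sv_aorta_ml"] = sv
        if cond.heart_rate_bpm:
            row["cardiac_output_l_min"] = hemo.cardiac_output(
                sv, cond.heart_rate_bpm)
        if cond.lv_volume:
            df = read_timeseries(root / cond.lv_volume)
            lv = LVVolumeCurve(time_s=df["time_s"].to_numpy(),
                               volume_ml=df["volume_ml"].to_numpy())
            sv_lv = hemo.lv_stroke_volume(lv)
            row["sv_lv_ml"] = sv_lv
            row["regurgitant_fraction"] = hemo.regurgitant_fraction(sv_lv, sv)
    if cond.first_pass:
        df = read_timeseries(root / cond.first_pass)
        curves = FirstPassCurves(time_s=df["time_s"].to_numpy(),
                                 rv=df["rv"].to_numpy(),
                                 lv=df["lv"].to_numpy())
        ptt = hemo.pulmonary_transit_time(curves)
        row["ptt_s"] = ptt
        if "cardiac_output_l_min" in row:
            row["pbv_ml"] = hemo.pulmonary_blood_volume(
                ptt, row["cardiac_output_l_min"])
    return row
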