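"""End-to-end orchestration of the validation workflow on synthetic data.

Stages mirror the validation design: simulate paired acquisitions of the
printed phantom and the reference column, measure CNR-depth profiles, fit the
SC-CNR and cross-phantom calibrations, and summarize (simulated or real)
observer thresholds.  Every artifact embeds the config hash and master seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .calibration import (
    CalibrationModel,
    fit_cross_phantom,
    fit_linear,
    fit_sc_cnr,
)
from .config import StudyConfig
from .geometry import PhantomModel
from .observer import (
    readings_to_frame,
    simulate_observer_readings,
    summarize,
    thresholds_to_cnr_sc,
    wilcoxon_exact,
)
from .roi import cnr_depth_profile, profile_to_frame
from .simulate import read_dicom, simulate_frame, write_dicom
from .spectrum import subject_contrast

log = logging.getLogger("lcphantom")

__all__ = [
    "simulate_batch",
    "analyze_manifest",
    "theoretical_sc_table",
    "calibrate_study",
    "report_study",
    "run_all",
]


def _provenance(cfg: StudyConfig) -> str:
    return f"# config_hash={cfg.config_hash()} master_seed={cfg.master_seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, cfg: StudyConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        df.to_csv(fh, index=False)


def simulate_batch(cfg: StudyConfig, out_dir: Path | None = None) -> pd.DataFrame:
    """Simulate every (phantom, beam, replicate) frame; write DICOM + manifest."""
    out = Path(out_dir or cfg.output_dir)
    frames_dir = out / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    det = cfg.detector_model()
    rows = []
    index = 0
    for phantom_name in cfg.phantoms:
        phantom = cfg.phantom(phantom_name)
        for beam_name in cfg.beams:
            for rep in range(cfg.replicates):
                seed = cfg.master_seed + index
                acq = cfg.acquisition_for(beam_name, seed)
                frame = simulate_frame(phantom, det, acq)
                fname = f"{phantom_name}_{beam_name}_r{rep:02d}.dcm"
                write_dicom(frame, frames_dir / fname)
                rows.append(
                    {
                        "path": str(Path("frames") / fname),
                        "phantom": phantom_name,
                        "beam": beam_name,
                        "replicate": rep,
                        "seed": seed,
                        "air_kerma_rate_uGy_min": acq.air_kerma_rate,
                        "exposure_time_s": acq.exposure_time,
                    }
                )
                log.info("simulated %s (seed %d)", fname, seed)
                index += 1
    manifest = pd.DataFrame(rows)
    _write_csv(manifest, out / "manifest.csv", cfg)
    return manifest


def analyze_manifest(cfg: StudyConfig, out_dir: Path | None = None) -> dict:
    """Measure CNR-depth profiles for every (phantom, beam) in the manifest.

    Returns {(phantom, beam): profile DataFrame}; missing frames are reported
    per row and skipped.
    """
    out = Path(out_dir or cfg.output_dir)
    manifest = pd.read_csv(out / "manifest.csv", comment="#")
    if manifest.empty:
        raise ValueError("manifest is empty: nothing to analyze")
    protocol = cfg.cnr_protocol()
    profiles: dict = {}
    errors = []
    for (phantom_name, beam_name), group in manifest.groupby(["phantom", "beam"]):
        phantom = cfg.phantom(phantom_name)
        frames = []
        for _, row in group.iterrows():
            path = out / row["path"]
            try:
                frames.append(read_dicom(path))
            except Exception as exc:  # report, continue
                errors.append((str(path), str(exc)))
                log.error("failed to read %s: %s", path, exc)
        if not frames:
            continue
        profile = cnr_depth_profile(frames, phantom, protocol)
        df = profile_to_frame(profile)
        _write_csv(df, out / f"cnr_{phantom_name}_{beam_name}.csv", cfg)
        profiles[(phantom_name, beam_name)] = df
    if errors:
        log.warning("%d frames could not be analyzed", len(errors))
    profiles["_errors"] = errors
    return profiles


def theoretical_sc_table(
    phantom: PhantomModel, beam_names, background_thickness_mm: float | None = None
) -> pd.DataFrame:
    """Spectral subject contrast per hole depth and beam for a phantom."""
    from .spectrum import DEFAULT_BEAMS

    thickness = background_thickness_mm or phantom.plate_thickness
    rows = []
    for beam_name in beam_names:
        beam = DEFAULT_BEAMS[beam_name]
        for depth in phantom.depths:
            rows.append(
                {
                    "beam": beam_name,
                    "depth_mm": depth,
                    "sc_percent": subject_contrast(
                        beam, phantom.material, thickness, depth
                    ),
                }
            )
    return pd.DataFrame(rows)


def calibrate_study(cfg: StudyConfig, out_dir: Path | None = None) -> dict:
    """Fit the calibration chain per beam from the measured CNR tables.

    Returns {beam: {"model": CalibrationModel, "lc_depth_fit": LinearFit,
    "ref_depth_fit": LinearFit}}.
    """
    out = Path(out_dir or cfg.output_dir)
    ref = cfg.phantom(cfg.reference_phantom)
    sc_table = theoretical_sc_table(ref, cfg.beams)
    results = {}
    for beam_name in cfg.beams:
        lc_csv = out / f"cnr_{cfg.lc_phantom}_{beam_name}.csv"
        ref_csv = out / f"cnr_{cfg.reference_phantom}_{beam_name}.csv"
        if not lc_csv.exists() or not ref_csv.exists():
            raise FileNotFoundError(
                f"missing CNR tables for beam {beam_name}: run analyze first"
            )
        lc = pd.read_csv(lc_csv, comment="#")
        refd = pd.read_csv(ref_csv, comment="#")
        sc = sc_table[sc_table["beam"] == beam_name].set_index("depth_mm")["sc_percent"]

        sc_fit = fit_sc_cnr(
            sc.loc[refd["depth_mm"]].to_numpy(), refd["cnr"].to_numpy()
        )
        cross = fit_cross_phantom(
            dict(zip(lc["depth_mm"], lc["cnr"])),
            dict(zip(refd["depth_mm"], refd["cnr"])),
        )
        model = CalibrationModel(beam=beam_name, sc_cnr_fit=sc_fit, cross_fit=cross)
        model.save(out / f"calibration_{beam_name}.yaml")
        entry = {
            "model": model,
            "lc_depth_fit": fit_linear(lc["depth_mm"], lc["cnr"]),
            "ref_depth_fit": fit_linear(refd["depth_mm"], refd["cnr"]),
        }
        log.info(
            "%s: SC = %.3f*CNR%+.3f (R2=%.3f); CNR_lc = %.3f*CNR_ref%+.3f (R2=%.3f)",
            beam_name,
            sc_fit.slope, sc_fit.intercept, sc_fit.r_squared,
            cross.slope, cross.intercept, cross.r_squared,
        )
        results[beam_name] = entry
    return results


def report_study(
    cfg: StudyConfig,
    calibrations: dict,
    readings=None,
    out_dir: Path | None = None,
) -> pd.DataFrame:
    """Threshold summaries with CNR/SC conversions and paired Wilcoxon tests.

    When ``readings`` is None, simulated observers are generated from the
    fitted CNR-depth lines (visibility criterion + per-observer jitter).
    """
    out = Path(out_dir or cfg.output_dir)
    obs_cfg = cfg.observer
    if readings is None:
        readings = []
        rng_base = cfg.master_seed * 1000
        for i, beam_name in enumerate(cfg.beams):
            cal = calibrations[beam_name]
            for j, (phantom_name, fit_key) in enumerate(
                [(cfg.lc_phantom, "lc_depth_fit"), (cfg.reference_phantom, "ref_depth_fit")]
            ):
                readings += simulate_observer_readings(
                    phantom_name,
                    cfg.phantom(phantom_name).depths,
                    calibrations[beam_name][fit_key],
                    beam=beam_name,
                    unit="SIM",
                    criterion_cnr=float(obs_cfg.get("criterion_cnr", 1.2)),
                    n_observers=int(obs_cfg.get("n_observers", 5)),
                    jitter_sd_mm=float(obs_cfg.get("jitter_sd_mm", 0.15)),
                    seed=rng_base + 10 * i + j,
                )
    df = readings_to_frame(readings)
    rows = []
    for (unit, beam_name, phantom_name), sub in df.groupby(["unit", "beam", "phantom"]):
        s = summarize(sub["limiting_depth_mm"].tolist())
        cal = calibrations.get(beam_name)
        row = {
            "unit": unit,
            "beam": beam_name,
            "phantom": phantom_name,
            "mean_depth_mm": s.mean_depth,
            "sd_depth_mm": s.sd_depth,
            "ci95_low_mm": s.ci95[0],
            "ci95_high_mm": s.ci95[1],
            "n_observers": s.n_observers,
        }
        if cal is not None:
            fit_key = "lc_depth_fit" if phantom_name == cfg.lc_phantom else "ref_depth_fit"
            conv = thresholds_to_cnr_sc(s, cal[fit_key], cal["model"])
            row.update(
                cnr_mean=conv.cnr_mean,
                cnr_sd=conv.cnr_sd,
                sc_mean_percent=conv.sc_mean,
                sc_sd_percent=conv.sc_sd,
            )
        rows.append(row)
    summary = pd.DataFrame(rows)

    tests = []
    for (unit, beam_name), sub in df.groupby(["unit", "beam"]):
        piv = sub.pivot_table(
            index="observer_id", columns="phantom", values="limiting_depth_mm"
        )
        if {cfg.lc_phantom, cfg.reference_phantom} <= set(piv.columns):
            res = wilcoxon_exact(
                piv[cfg.lc_phantom].to_numpy(), piv[cfg.reference_phantom].to_numpy()
            )
            tests.append(
                {
                    "unit": unit,
                    "beam": beam_name,
                    "wilcoxon_w": res.statistic,
                    "p_value": res.p_value,
                    "n_effective": res.n_effective,
                }
            )
    tests_df = pd.DataFrame(tests)
    _write_csv(summary, out / "threshold_summary.csv", cfg)
    if not tests_df.empty:
        _write_csv(tests_df, out / "wilcoxon_tests.csv", cfg)
    return summary


def run_all(cfg: StudyConfig, readings=None) -> pd.DataFrame:
    """simulate -> analyze -> calibrate -> report, returning the summary."""
    simulate_batch(cfg)
    analyze_manifest(cfg)
    calibrations = calibrate_study(cfg)
    return report_study(cfg, calibrations, readings=readings)
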