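"""Pipeline driver: simulate -> classify -> cytocochleogram -> quantify -> associate.

Mirrors the study design: measure ABR thresholds, classify animals against the
age-matched reference cohort, map hair-cell survival and channel expression in
the classified animals, and regress the outcomes on absolute age.
"""

from __future__ import annotations

import json
import logging
import math
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import abr, association, io, synth
from .cochleogram import band_loss, bin_cytocochleogram, build_spiral_map, place_frequency_map
from .config import RunConfig

log = logging.getLogger("presbycusis")


class PipelineError(RuntimeError):
    """Stage failure with the stage name and input provenance."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


def _setup_logging(output_dir: Path) -> None:
    output_dir.mkdir(parents=True, exist_ok=True)
    log.setLevel(logging.INFO)
    log.handlers.clear()
    for h in (logging.StreamHandler(sys.stderr),
              logging.FileHandler(output_dir / "run.log", mode="w")):
        h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(h)


def simulate(config: RunConfig) -> None:
    """Write a synthetic study to the input directory: a threshold cohort,
    spiral marker files for a few subjects, and fluorescence image pairs."""
    indir = Path(config.input_dir)
    indir.mkdir(parents=True, exist_ok=True)
    params = synth.CohortSimParams(seed=config.seed)
    grids, truth = synth.gen_cohort(params)
    io.write_threshold_csv(grids, indir / "thresholds.csv")
    truth.labels.to_csv(indir / "ground_truth_cohort.csv", index=False)

    profile = synth.step_loss(50.0, 0.3)
    for i, sid in enumerate(truth.labels["subject_id"].iloc[:2]):
        traces, struth = synth.gen_spiral(synth.SpiralSimParams(
            loss_profile=profile, seed=config.seed + 1 + i))
        io.write_marker_csv(traces, indir / f"markers_{sid}.csv")
        io.write_invalid_spans_csv(traces, indir / f"invalid_spans_{sid}.csv")
        struth.bin_loss.to_csv(indir / f"ground_truth_spiral_{sid}.csv", index=False)

    rows = []
    for i, (label, n_ohc) in enumerate((("lower", 5), ("upper", 5))):
        fp = synth.FluorSimParams(
            structure=synth.PunctaSpec(n=10 if label == "lower" else 5,
                                       sigma=1.5, amplitude=150.0),
            background=(8.0, 0.0, 0.0), noise_sd=4.0, n_ohc=n_ohc,
            seed=config.seed + 10 + i)
        noisy, truth_f = synth.gen_fluor(fp)
        name = f"fluor_{label}.tif"
        io.write_tiff(noisy, indir / name)
        rows.append((name, "n_ohc", n_ohc, "", "apical", label,
                     truth_f.normalized_clean))
    pd.DataFrame(rows, columns=["image", "normalizer_kind", "n_ohc",
                                "sv_length", "turn", "quartile",
                                "true_normalized"]).to_csv(
        indir / "quant_manifest.csv", index=False)
    log.info("simulated cohort (%d grids), 2 spirals, 2 fluorescence images",
             len(grids))


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage found in the input directory; returns and
    writes the report.  Deterministic given the config and its seed."""
    indir, outdir = Path(config.input_dir), Path(config.output_dir)
    _setup_logging(outdir)
    log.info("resolved config: %s", json.dumps(config.resolved(), sort_keys=True))
    report: dict = {"config": config.resolved()}

    thr_path = indir / "thresholds.csv"
    if not thr_path.exists():
        raise PipelineError("abr", f"no thresholds.csv in {indir}")
    try:
        grids = io.read_threshold_csv(thr_path)
    except Exception as exc:
        raise PipelineError("abr", f"{thr_path}: {exc}") from exc
    if not grids:
        raise PipelineError("abr", f"{thr_path} contains no grids")

    # --- reference distributions, classification, shifts -------------------
    try:
        refs = {g: abr.build_reference(grids, g)
                for g in sorted({x.age_group for x in grids})}
        juv = refs.get("juvenile")
        label_rows, shift_rows = [], []
        for g in abr.collapse_ears(grids):
            lab = abr.classify_quartile(g, refs[g.age_group],
                                        rule=config.quartile_rule,
                                        outside_fraction=config.outside_fraction)
            row = {"subject_id": g.subject_id, "age_group": g.age_group,
                   "age_days": g.age_days, "label": lab.label, "score": lab.score}
            if juv is not None:
                sh = abr.threshold_shift(g, juv)
                row["low_band_shift_db"] = sh.low_band_mean
                row["high_band_shift_db"] = sh.high_band_mean
                shift_rows.append(row)
            label_rows.append(row)
        labels = pd.DataFrame(label_rows)
        labels.to_csv(outdir / "quartiles.csv", index=False)
        for g, ref in refs.items():
            abr.summarize_groups(
                [x for x in abr.collapse_ears(grids) if x.age_group == g]
            ).to_csv(outdir / f"summary_{g}.csv", index=False)
        report["abr"] = {
            "n_subjects": len(labels),
            "labels": labels["label"].value_counts().to_dict(),
        }
        log.info("classified %d subjects", len(labels))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("abr", str(exc)) from exc

    # --- cytocochleograms ---------------------------------------------------
    pfmap = place_frequency_map(config.place_map_preset)
    cyto_summaries = {}
    for mpath in sorted(indir.glob("markers_*.csv")):
        sid = mpath.stem.removeprefix("markers_")
        try:
            span_path = indir / f"invalid_spans_{sid}.csv"
            spans = io.read_invalid_spans_csv(span_path) if span_path.exists() else {}
            traces = io.read_marker_csv(mpath, config.scale_um_per_px, spans)
            by_label = {t.label: t for t in traces}
            spiral = build_spiral_map(by_label["apical"], by_label["middle"],
                                      by_label["basal"],
                                      config.marker_max_distance_um)
            cyto = bin_cytocochleogram(spiral)
            io.write_cytocochleogram_csv(cyto, pfmap,
                                         outdir / f"cytocochleogram_{sid}.csv")
            bl = band_loss(cyto, pfmap, "OHC", config.weighted_band_mean,
                           config.band_split_khz)
            cyto_summaries[sid] = {
                "total_length_um": spiral.total_length_um,
                "ohc_low_band_loss_pct": bl.low_pct,
                "ohc_high_band_loss_pct": bl.high_pct,
            }
            log.info("cytocochleogram %s: length %.0f µm, OHC loss low %.1f%% "
                     "high %.1f%%", sid, spiral.total_length_um,
                     bl.low_pct, bl.high_pct)
        except Exception as exc:
            raise PipelineError("cochleogram", f"{mpath}: {exc}") from exc
    if cyto_summaries:
        report["cytocochleogram"] = cyto_summaries

    # --- fluorescence quantification ---------------------------------------
    manifest = indir / "quant_manifest.csv"
    if manifest.exists():
        from .fluorquant import quantify

        quant_rows = []
        try:
            for r in pd.read_csv(manifest).itertuples():
                img = io.read_tiff(indir / r.image)
                roi_path = indir / f"rois_{Path(r.image).stem}.csv"
                if roi_path.exists():
                    rois = io.read_roi_csv(roi_path)
                else:
                    h, w = img.data.shape
                    from .fluorquant import RoiSpec
                    rois = [RoiSpec("rectangle", x0=0, y0=0, width=w, height=h)]
                n_ohc = int(r.n_ohc) if r.normalizer_kind == "n_ohc" else None
                sv_len = (float(r.sv_length)
                          if r.normalizer_kind == "sv_length" else None)
                q = quantify(img, rois, r.normalizer_kind, n_ohc=n_ohc,
                             sv_length=sv_len,
                             radius=config.rolling_ball_radius,
                             floor=config.floor_threshold,
                             eight_bit_mode=config.eight_bit_mode,
                             turn=str(r.turn), quartile=str(r.quartile))
                quant_rows.append({"image": r.image, "turn": q.turn,
                                   "quartile": q.quartile, "auc": q.auc,
                                   "normalizer": q.normalizer,
                                   "normalized_intensity": q.normalized_intensity})
        except Exception as exc:
            raise PipelineError("quantify", f"{manifest}: {exc}") from exc
        qdf = pd.DataFrame(quant_rows)
        qdf.to_csv(outdir / "quantification.csv", index=False)
        report["quantification"] = quant_rows
        log.info("quantified %d images", len(quant_rows))

    # --- age associations ----------------------------------------------------
    try:
        if shift_rows:
            sdf = pd.DataFrame(shift_rows)
            fits = {}
            for lab, sub in sdf.groupby("label"):
                sub = sub.dropna(subset=["high_band_shift_db"])
                if len(sub) >= 3 and sub["age_days"].nunique() > 1:
                    fit = association.ols_fit(sub["age_days"], sub["high_band_shift_db"])
                    fits[lab] = {"slope_per_50d": fit.slope_per_50d,
                                 "intercept": fit.intercept,
                                 "r_squared": fit.r_squared,
                                 "pearson_r": fit.pearson_r,
                                 "p_value": fit.p_value, "n": fit.n}
            report["association"] = fits
            with open(outdir / "regressions.json", "w", encoding="utf-8") as fh:
                json.dump(fits, fh, indent=2, sort_keys=True, allow_nan=True)
    except Exception as exc:
        raise PipelineError("associate", str(exc)) from exc

    def _clean(o):
        if isinstance(o, dict):
            return {k: _clean(v) for k, v in o.items()}
        if isinstance(o, list):
            return [_clean(v) for v in o]
        if isinstance(o, float) and math.isnan(o):
            return None
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return o

    report = _clean(report)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("report written to %s", outdir / "report.json")
    return report
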