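"""End-to-end orchestration: synthetic generation -> segmentation -> GP ->
expression and marker statistics -> phenotype calls, in one seeded run.

Every output table carries a ``#``-prefixed metadata header (package
version, seed, config hash) so re-runs are attributable; the whole run is
byte-deterministic under a fixed config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (classify_by_gp, feature_matrix_from_table,
                       logistic_training_accuracy, pca_project)
from .config import PipelineConfig
from .cytometry import marker_profile
from .gp import (CalibrationReference, gp_pixelwise, summaries_to_frame,
                 summarize_roi)
from .segmentation import segment_membranes
from .stats import compare_groups, group_stats
from .synthetic import (default_expression_spec, generate_calibration_set,
                        generate_expression_table, generate_mfi_table,
                        generate_phenotype_fields)

__all__ = ["run_all", "PipelineResult", "write_table"]

log = logging.getLogger("macpheno")


@dataclass
class PipelineResult:
    calls: pd.DataFrame            # method, sample, phenotype, call
    gp_summaries: pd.DataFrame | None
    expression_groups: pd.DataFrame | None
    marker_comparisons: pd.DataFrame | None
    g_factor: float | None
    report: dict


def write_table(frame: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    """CSV with a metadata header recording provenance."""
    header = (f"# macpheno {__version__}\n"
              f"# seed={config.seed}\n"
              f"# config_hash={config.config_hash()}\n")
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)


def _gp_stage(config: PipelineConfig, out: Path | None) -> tuple[pd.DataFrame, float]:
    im = config.imaging
    calib = generate_calibration_set(im.gp_ref, im.gp_mes, im.n_vesicles,
                                     im.calibration_noise_sd,
                                     seed=(config.seed * 17 + 5) % (2**31))
    ref = CalibrationReference.from_intensity_pairs(calib.pairs, gp_ref=im.gp_ref)
    log.info("calibration: gp_ref=%.4f gp_mes_hat=%.4f G=%.4f",
             ref.gp_ref, ref.gp_mes, ref.g_factor)
    fields = generate_phenotype_fields(
        n_cells=im.n_cells_per_group, photon_budget=im.photon_budget,
        background_rate=im.background_rate, seed=config.seed)
    seg = config.segmentation
    summaries = []
    for phen, field_ in fields.items():
        rois = segment_membranes(field_.channels, min_roi_px=seg.min_roi_px,
                                 ring_width=seg.ring_width,
                                 keep_border=seg.keep_border)
        gp_map = gp_pixelwise(field_.channels, ref.g_factor,
                              config.imaging.intensity_floor)
        for roi in rois:
            summaries.append(summarize_roi(gp_map, roi.mask,
                                           cell_id=f"{phen}_{roi.cell_id}",
                                           phenotype=phen))
        if out is not None:
            import tifffile

            from .gp import render_gp_map, write_channel_pair
            write_channel_pair(out / f"field_{phen}.tif", field_.channels)
            tifffile.imwrite(out / f"gp_map_{phen}.tif",
                             gp_map.gp.astype(np.float32))
            rgb = render_gp_map(gp_map, field_.channels,
                                gp_range=(im.gp_range_low, im.gp_range_high),
                                brightness_percentile=im.brightness_percentile)
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            plt.imsave(out / f"gp_render_{phen}.png", rgb)
    frame = summaries_to_frame(summaries)
    return frame, ref.g_factor


def run_all(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run every enabled stage and assemble the combined phenotype-call table.

    Stage failures propagate as exceptions naming the stage. With
    ``out_dir`` set, per-stage tables, images and a JSON report are written.
    """
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "config_hash": config.config_hash()}
    calls = []
    gp_frame = expr_groups = marker_comp = None
    g_factor = None

    if config.run_gp_stage:
        try:
            gp_frame, g_factor = _gp_stage(config, out)
        except Exception as exc:
            raise RuntimeError(f"GP stage failed: {exc}") from exc
        cls = config.classifier
        gp_calls = classify_by_gp(gp_frame, (cls.gp_threshold_low,
                                             cls.gp_threshold_high))
        calls.append(pd.DataFrame({
            "method": "gp", "sample": gp_calls["cell_id"],
            "phenotype": gp_calls["phenotype"], "call": gp_calls["call"]}))
        report["g_factor"] = g_factor
        report["n_cells_analyzed"] = int(len(gp_frame))
        group_means = gp_frame.groupby("phenotype")["mean_gp_reported"].mean()
        report["gp_group_means_reported"] = {k: float(v)
                                             for k, v in group_means.items()}
        if out is not None:
            write_table(gp_frame, out / "gp_summaries.csv", config)

    if config.run_expression_stage:
        try:
            spec = default_expression_spec(seed=(config.seed * 13 + 1) % (2**31))
            table = generate_expression_table(spec)
            feats = feature_matrix_from_table(table)
            clf_report = logistic_training_accuracy(
                feats, seed=config.seed,
                cv_folds=config.classifier.cv_folds or None)
            _, var_frac = pca_project(feats)
            expr_groups = (table.groupby(["gene", "phenotype"], as_index=False)
                           .agg(n=("value", "size"), mean=("value", "mean"),
                                sd=("value", "std")))
            expr_stats = _pairwise_stats(table, "gene", "value", config)
        except Exception as exc:
            raise RuntimeError(f"expression stage failed: {exc}") from exc
        import sklearn.pipeline  # noqa: F401  (predictions via refit below)
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from .classify import LOGISTIC_C, LOGISTIC_MAX_ITER, _split_features
        X, y, _ = _split_features(feats)
        pipe = make_pipeline(StandardScaler(),
                             LogisticRegression(C=LOGISTIC_C,
                                                max_iter=LOGISTIC_MAX_ITER,
                                                random_state=config.seed))
        pred = pipe.fit(X, y).predict(X)
        calls.append(pd.DataFrame({"method": "expression",
                                   "sample": feats.index, "phenotype": y,
                                   "call": pred}))
        report["expression_training_accuracy_pct"] = clf_report.training_accuracy
        report["expression_pc_variance_explained"] = [float(v) for v in var_frac]
        if out is not None:
            write_table(table, out / "expression.csv", config)
            write_table(expr_stats, out / "expression_stats.csv", config)

    if config.run_marker_stage:
        try:
            mfi = generate_mfi_table(seed=(config.seed * 19 + 7) % (2**31))
            profile = marker_profile(mfi, alpha=config.stats.alpha,
                                     variance_model="pooled")
            marker_comp = profile.comparisons
            mac = mfi[mfi["phenotype"] != "THP-1"]
            feats_m = feature_matrix_from_table(mac, value_col="mfi",
                                                feature_col="marker")
            from sklearn.linear_model import LogisticRegression
            from sklearn.pipeline import make_pipeline
            from sklearn.preprocessing import StandardScaler
            from .classify import LOGISTIC_C, LOGISTIC_MAX_ITER, _split_features
            Xm, ym, _ = _split_features(feats_m)
            pipe_m = make_pipeline(StandardScaler(),
                                   LogisticRegression(C=LOGISTIC_C,
                                                      max_iter=LOGISTIC_MAX_ITER,
                                                      random_state=config.seed))
            pred_m = pipe_m.fit(Xm, ym).predict(Xm)
        except Exception as exc:
            raise RuntimeError(f"marker stage failed: {exc}") from exc
        calls.append(pd.DataFrame({"method": "marker", "sample": feats_m.index,
                                   "phenotype": ym, "call": pred_m}))
        report["marker_elevated"] = {k: sorted(v)
                                     for k, v in profile.elevated.items()}
        if out is not None:
            write_table(mfi, out / "mfi.csv", config)
            write_table(marker_comp, out / "marker_profile.csv", config)

    if not calls:
        raise RuntimeError("all stages disabled: nothing to run")
    combined = pd.concat(calls, ignore_index=True)
    combined["correct"] = combined["phenotype"] == combined["call"]
    report["call_accuracy_by_method"] = {
        m: float(g["correct"].mean())
        for m, g in combined.groupby("method")}
    report["call_accuracy_overall"] = float(combined["correct"].mean())
    if out is not None:
        write_table(combined, out / "phenotype_calls.csv", config)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return PipelineResult(calls=combined, gp_summaries=gp_frame,
                          expression_groups=expr_groups,
                          marker_comparisons=marker_comp,
                          g_factor=g_factor, report=report)


def _pairwise_stats(table: pd.DataFrame, feature_col: str, value_col: str,
                    config: PipelineConfig) -> pd.DataFrame:
    """All pairwise phenotype contrasts per gene/marker, tidy output."""
    from itertools import combinations
    rows = []
    for feat, grp in table.groupby(feature_col, sort=True):
        groups = {p: group_stats(g[value_col].to_numpy(float), label=p)
                  for p, g in grp.groupby("phenotype")}
        for pa, pb in combinations(sorted(groups), 2):
            r = compare_groups(groups[pa], groups[pb],
                               variance_model=config.stats.variance_model)
            rows.append({feature_col: feat, "group_a": pa, "group_b": pb,
                         "mean_diff": r.mean_diff, "sem": r.sem_diff,
                         "t": r.t_stat, "df": r.df, "p": r.p_two_tailed,
                         "ci_low": r.ci_low, "ci_high": r.ci_high,
                         "r_squared": r.r_squared, "f": r.f_stat,
                         "f_p": r.f_p, "model": r.variance_model})
    return pd.DataFrame(rows)
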