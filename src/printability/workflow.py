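"""Batch orchestration, replicate aggregation, and statistics.

Replicate layouts follow the reference protocol: each structure is printed as
3 biological x 8 technical replicates (24 objects per formulation).  Per
formulation and metric the module reports mean, standard deviation and n,
checks normality with the Jarque-Bera test (alpha = 0.05), and compares
formulations with one-way ANOVA plus Tukey pairwise post-hoc comparisons;
p < 0.05 is flagged as significant, with no multiple-testing correction
across metrics.

Uncertainties of the normalized metrics are propagated with the first-order
Taylor method: for a linear combination ``y = sum_i c_i x_i`` of independent
inputs, ``sd(y) = sqrt(sum_i (c_i sd_i)**2)``.  The normalized metrics are
exactly linear in their measured inputs (``w_n = w/d``,
``r_n = (r_i + r_o)/(2 r_model)``, ``a_n = (a_i + a_o)/(2 a_model)``), so the
first-order result is exact there.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cytometry, imaging, metrics, rheology

__all__ = [
    "propagate_uncertainty",
    "propagated_sd_normalized_radii",
    "propagated_sd_normalized_angle",
    "propagated_sd_normalized_width",
    "AggregateResult",
    "aggregate",
    "BatchConfig",
    "analyze_structure_image",
    "run_pipeline",
]

log = logging.getLogger("printability")

ALPHA = 0.05


def propagate_uncertainty(coefficients: Sequence[float], sds: Sequence[float]) -> float:
    """First-order Taylor propagation for independent inputs.

    Returns ``sqrt(sum((c_i * sd_i)**2))``.
    """
    c = np.asarray(coefficients, dtype=float)
    s = np.asarray(sds, dtype=float)
    if c.ndim != 1 or c.shape != s.shape or c.size < 1:
        raise ValueError("invalid input: coefficient and sd sequences must match, length >= 1")
    if np.any(s < 0):
        raise ValueError("invalid input: standard deviations must be non-negative")
    return float(np.sqrt(np.sum((c * s) ** 2)))


def propagated_sd_normalized_radii(sd_ri: float, sd_ro: float, r_model: float) -> float:
    """sd of ``r_n = (r_i + r_o) / (2 r_model)``."""
    c = 1.0 / (2.0 * r_model)
    return propagate_uncertainty([c, c], [sd_ri, sd_ro])


def propagated_sd_normalized_angle(sd_ai: float, sd_ao: float, a_model: float) -> float:
    """sd of ``a_n = (a_i + a_o) / (2 a_model)``."""
    c = 1.0 / (2.0 * a_model)
    return propagate_uncertainty([c, c], [sd_ai, sd_ao])


def propagated_sd_normalized_width(sd_w: float, d_nozzle: float) -> float:
    """sd of ``w_n = w / d_nozzle``."""
    return propagate_uncertainty([1.0 / d_nozzle], [sd_w])


@dataclass(frozen=True)
class AggregateResult:
    """Per-group descriptive statistics and between-group comparisons.

    ``group_stats`` has one row per (formulation, metric): mean, sd, n and the
    Jarque-Bera normality p-value.  ``comparisons`` has one row per metric:
    the one-way ANOVA p-value across formulations, a significance flag at
    p < 0.05, and Tukey pairwise p-values as a JSON-encoded mapping.
    """

    group_stats: pd.DataFrame
    comparisons: pd.DataFrame


def aggregate(
    df: pd.DataFrame,
    value_cols: Sequence[str],
    group_col: str = "formulation",
) -> AggregateResult:
    """Summarize replicate metrics per formulation and test for differences."""
    if group_col not in df.columns:
        raise ValueError(f"no data for group: column {group_col!r} missing")
    rows = []
    comps = []
    for metric_col in value_cols:
        groups = []
        labels = []
        for label, g in df.groupby(group_col, sort=False):
            vals = g[metric_col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                raise ValueError(f"no data for group: {label!r} has no {metric_col!r} values")
            if vals.size >= 3 and np.ptp(vals) > 0:
                jb_p = float(stats.jarque_bera(vals).pvalue)
            else:
                jb_p = math.nan
            rows.append(
                {
                    group_col: label,
                    "metric": metric_col,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "n": int(vals.size),
                    "jarque_bera_p": jb_p,
                    "normal": bool(jb_p >= ALPHA) if not math.isnan(jb_p) else None,
                }
            )
            groups.append(vals)
            labels.append(label)
        if len(groups) >= 2 and all(v.size >= 2 for v in groups):
            pooled = np.concatenate(groups)
            if np.ptp(pooled) == 0:
                anova_p, applicable = math.nan, False
            else:
                anova_p = float(stats.f_oneway(*groups).pvalue)
                applicable = not math.isnan(anova_p)
            pairwise = {}
            if applicable and len(groups) >= 2:
                try:
                    tk = stats.tukey_hsd(*groups)
                    for (i, a), (j, b) in combinations(enumerate(labels), 2):
                        pairwise[f"{a} vs {b}"] = float(tk.pvalue[i, j])
                except ValueError:
                    pairwise = {}
            comps.append(
                {
                    "metric": metric_col,
                    "anova_p": anova_p,
                    "anova_applicable": applicable,
                    "significant": bool(applicable and anova_p < ALPHA),
                    "pairwise_p": json.dumps(pairwise, sort_keys=True),
                }
            )
    return AggregateResult(group_stats=pd.DataFrame(rows), comparisons=pd.DataFrame(comps))


# --------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class BatchConfig:
    """Batch layout and processing parameters, loadable from JSON.

    ``images`` entries: ``{"path", "kind", "formulation", "replicate"}`` plus
    optional CAD overrides; ``curves`` entries: ``{"path", "formulation"}``;
    ``events`` entries: ``{"path", "formulation", "control"}``.
    """

    images: tuple[dict, ...] = ()
    curves: tuple[dict, ...] = ()
    events: tuple[dict, ...] = ()
    px_per_mm: float = imaging.DEFAULT_PX_PER_MM
    median_window: int = 3
    threshold_window: int | None = None
    threshold_offset: float | None = None
    min_area_mm2: float = 0.2
    cad: dict = field(default_factory=dict)
    fit_range: tuple[float, float] = (1.0, math.inf)
    seed: int = 0
    output_dir: str = "printability_out"

    @classmethod
    def from_json(cls, path) -> "BatchConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("images", "curves", "events"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "fit_range" in raw:
            raw["fit_range"] = tuple(raw["fit_range"])
        return cls(**raw)


def analyze_structure_image(
    image: imaging.GrayImage,
    cad: metrics.CadTarget,
    median_window: int = 3,
    threshold_window: int | None = None,
    threshold_offset: float | None = None,
    min_area_mm2: float = 0.2,
) -> dict:
    """Full single-image chain: binarize -> segment -> per-kind metrics.

    Returns a flat record suitable for a metrics table row.
    """
    mask = imaging.binarize(
        image,
        median_window=median_window,
        threshold_window=threshold_window,
        threshold_offset=threshold_offset,
    )
    comps = imaging.segment(mask, min_area_mm2=min_area_mm2)
    rec: dict = {"kind": cad.kind, "n_components": len(comps.components)}
    if cad.kind == "line":
        m = metrics.analyze_line(comps, cad)
        rec.update(
            w_n=m.normalized_width,
            l_n=m.normalized_length,
            width_mm=m.width,
            length_mm=m.length,
            segment_count=m.segment_count,
            interrupted=m.interrupted,
        )
    elif cad.kind == "circle":
        m = metrics.analyze_circle(comps, cad)
        rec.update(
            w_n=m.normalized_width,
            r_n=m.normalized_radii,
            inner_radius_mm=m.inner_radius,
            outer_radius_mm=m.outer_radius,
            width_mm=m.width_at_180,
        )
    else:
        m = metrics.analyze_angle(comps, cad)
        rec.update(w_n=m.normalized_width, width_mm=m.width)
        for v in m.vertices:
            rec[f"a_n_{int(round(v.designed))}"] = v.normalized
    return rec


def run_pipeline(config: BatchConfig) -> dict:
    """Run the full batch: images, flow curves, and cytometry files.

    Writes ``metrics.csv``, ``aggregate.csv``, ``viability.csv`` and
    ``report.json`` into ``config.output_dir``.  Failures of individual items
    are logged and recorded; the remaining items are still processed.  The
    returned report dict contains an ``"errors"`` list and is written to
    ``report.json``; callers turning it into an exit code should treat a
    non-empty error list as failure.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"errors": [], "n_images": 0, "n_curves": 0, "n_event_files": 0}
    metric_rows = []
    for item in config.images:
        try:
            img = imaging.read_image(item["path"], px_per_mm=item.get("px_per_mm", config.px_per_mm))
            cad = metrics.CadTarget(kind=item["kind"], **config.cad)
            rec = analyze_structure_image(
                img,
                cad,
                median_window=config.median_window,
                threshold_window=config.threshold_window,
                threshold_offset=config.threshold_offset,
                min_area_mm2=config.min_area_mm2,
            )
            rec["formulation"] = item.get("formulation", "")
            rec["replicate"] = item.get("replicate", "")
            rec["path"] = str(item["path"])
            metric_rows.append(rec)
            report["n_images"] += 1
        except Exception as exc:  # error isolation: keep processing the batch
            log.error("image %s failed: %s", item.get("path"), exc)
            report["errors"].append({"item": str(item.get("path")), "error": str(exc)})
    metrics_df = pd.DataFrame(metric_rows)
    metrics_df.to_csv(out / "metrics.csv", index=False)

    if not metrics_df.empty and metrics_df["formulation"].nunique() >= 1:
        value_cols = [
            c for c in ("w_n", "l_n", "r_n", "a_n_30", "a_n_45", "a_n_60") if c in metrics_df
        ]
        try:
            agg = aggregate(metrics_df, value_cols)
            agg.group_stats.merge(agg.comparisons, on="metric", how="left").to_csv(
                out / "aggregate.csv", index=False
            )
            report["aggregate"] = {
                "metrics": value_cols,
                "significant": agg.comparisons.set_index("metric")["significant"].to_dict(),
            }
        except ValueError as exc:
            report["errors"].append({"item": "aggregate", "error": str(exc)})

    fit_rows = []
    for item in config.curves:
        try:
            curves = rheology.read_viscosity_csv(item["path"])
            model = rheology.fit_power_law(curves, fit_range=config.fit_range)
            fit_rows.append(
                {
                    "formulation": item.get("formulation", ""),
                    "n": model.n,
                    "K": model.K,
                    "r_squared": model.fit_quality,
                }
            )
            report["n_curves"] += 1
        except Exception as exc:
            log.error("curve %s failed: %s", item.get("path"), exc)
            report["errors"].append({"item": str(item.get("path")), "error": str(exc)})
    if fit_rows:
        pd.DataFrame(fit_rows).to_csv(out / "rheology.csv", index=False)
        report["rheology"] = fit_rows

    via_rows = []
    for item in config.events:
        try:
            table = cytometry.read_events(item["path"])
            cfg = cytometry.GatingConfig()
            if item.get("control"):
                control = cytometry.read_events(item["control"])
                red_thr = cytometry.derive_dead_threshold(control, config=cfg)
                cfg = cytometry.GatingConfig(
                    fsc_bounds=cfg.fsc_bounds,
                    ssc_bounds=cfg.ssc_bounds,
                    green_threshold=cfg.green_threshold,
                    red_threshold=red_thr,
                )
            res = cytometry.viability(cytometry.gate(table, cfg))
            via_rows.append(
                {
                    "formulation": item.get("formulation", ""),
                    "path": str(item["path"]),
                    "n_live": res.n_live,
                    "n_dead": res.n_dead,
                    "viability": res.viability,
                    "fraction_excluded": res.fraction_excluded,
                }
            )
            report["n_event_files"] += 1
        except Exception as exc:
            log.error("events %s failed: %s", item.get("path"), exc)
            report["errors"].append({"item": str(item.get("path")), "error": str(exc)})
    if via_rows:
        pd.DataFrame(via_rows).to_csv(out / "viability.csv", index=False)

    report["note"] = "per-comparison alpha 0.05; no multiple-testing correction applied"
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
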