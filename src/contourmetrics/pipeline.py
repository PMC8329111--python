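"""Batch evaluation: metric panels per case, cohort summaries, associations.

``compute_panel`` evaluates the full configured metric panel on one
(auto, corrected) pair, sharing boundary extraction and nearest-distance
computation across all tolerances and percentiles. ``run_batch`` maps it
over a case manifest, continuing past per-case failures (which become
error rows, never silent omissions). ``summarize_panel`` reports
median / range / IQR per metric — the summary statistics appropriate for
the non-normal distributions these metrics produce — with
linear-interpolation quartiles. ``run_association`` couples the panel to a
case table of correction times and covariates via the nonparametric tests.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .boundary_geometry import extract_boundary_3d, nearest_distances
from .boundary_metrics import (
    added_path_length,
    average_surface_distance_from_sets,
    false_negative_path_length,
    surface_dsc_from_sets,
)
from .config import PanelConfig
from .errors import ContourMetricsError, DegenerateInputError
from .mask_io import BinaryMask, CaseManifest, load_mask
from .overlap_metrics import (
    false_negative_volume,
    jaccard_index,
    overlap_counts,
    volumetric_dsc,
)
from .stats_analysis import (
    AssociationResult,
    kruskal_wallis_with_posthoc,
    mann_whitney_u,
    metric_time_correlation_table,
    results_to_frame,
    spearman,
)

__all__ = ["compute_panel", "run_batch", "summarize_panel", "run_association"]


def compute_panel(
    auto: BinaryMask,
    corrected: BinaryMask,
    config: PanelConfig | None = None,
    case_id: str = "",
) -> dict:
    """All configured metrics for one (auto, corrected) pair, as one flat
    dict (one row of the batch output). Empty-mask conventions: volumetric
    metrics use the 1/0 conventions; surface metrics are NaN with a warning
    when either mask has no surface."""
    cfg = config or PanelConfig()
    warnings: list[str] = []
    if auto.nonorthogonal_affine or corrected.nonorthogonal_affine:
        warnings.append("nonorthogonal_affine")

    row: dict = {"case_id": case_id}
    counts = overlap_counts(auto, corrected)  # raises GeometryError if not comparable
    row["volumetric_dsc"] = volumetric_dsc(auto, corrected)
    row["jaccard"] = jaccard_index(auto, corrected)
    row["fnv_px"] = false_negative_volume(auto, corrected)
    row["apl_px"] = added_path_length(auto, corrected, mode=cfg.apl_mode)
    row["fnpl_px"] = false_negative_path_length(auto, corrected, mode=cfg.apl_mode)

    if counts.n_a == 0 or counts.n_b == 0:
        warnings.append("empty_mask_surface_metrics_undefined")
        for tau in cfg.surface_dsc_tolerances_mm:
            row[cfg.tau_column(tau)] = math.nan
        for p in cfg.hausdorff_percentiles:
            row[cfg.hd_column(p)] = math.nan
        row["asd_mm"] = math.nan
    else:
        surf_a = extract_boundary_3d(auto, mode=cfg.surface_boundary_mode)
        surf_b = extract_boundary_3d(corrected, mode=cfg.surface_boundary_mode)
        surf_d = nearest_distances(surf_a, surf_b)
        for tau in cfg.surface_dsc_tolerances_mm:
            row[cfg.tau_column(tau)] = surface_dsc_from_sets(surf_a, surf_b, tau, dists=surf_d)
        if cfg.distance_boundary_mode == cfg.surface_boundary_mode:
            dist_d = surf_d
        else:
            pa = extract_boundary_3d(auto, mode=cfg.distance_boundary_mode)
            pb = extract_boundary_3d(corrected, mode=cfg.distance_boundary_mode)
            dist_d = nearest_distances(pa, pb)
        pooled = dist_d.pooled
        for p in cfg.hausdorff_percentiles:
            row[cfg.hd_column(p)] = (
                float(pooled.max()) if p == 100.0 else float(np.percentile(pooled, p))
            )
        row["asd_mm"] = average_surface_distance_from_sets(dist_d)

    row["warnings"] = ";".join(warnings)
    _assert_panel_invariants(row, cfg)
    return row


def _assert_panel_invariants(row: dict, cfg: PanelConfig) -> None:
    sims = ["volumetric_dsc", "jaccard"] + [
        cfg.tau_column(t) for t in cfg.surface_dsc_tolerances_mm
    ]
    for c in sims:
        v = row[c]
        if not math.isnan(v) and not 0.0 <= v <= 1.0 + 1e-12:
            raise AssertionError(f"similarity {c}={v} outside [0,1]")
    dists = [cfg.hd_column(p) for p in cfg.hausdorff_percentiles] + ["asd_mm"]
    for c in dists:
        v = row[c]
        if not math.isnan(v) and v < 0:
            raise AssertionError(f"distance {c}={v} < 0")
    if row["fnpl_px"] > row["apl_px"]:
        raise AssertionError("FNPL exceeds APL")


def run_batch(
    manifest: CaseManifest, config: PanelConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate the panel for every manifest case. Returns (panel, summary);
    cases that fail carry their error message in the ``error`` column and
    NaN metrics, and the run continues."""
    cfg = config or PanelConfig()
    rows = []
    for case_id, auto_path, corrected_path in manifest:
        try:
            auto = load_mask(auto_path)
            corrected = load_mask(corrected_path)
            row = compute_panel(auto, corrected, cfg, case_id=case_id)
            row["error"] = ""
        except (ContourMetricsError, OSError) as exc:
            row = {"case_id": case_id, "error": f"{type(exc).__name__}: {exc}",
                   "warnings": ""}
        rows.append(row)
    panel = pd.DataFrame(rows)
    for col in cfg.metric_columns():  # keep schema stable even if all cases fail
        if col not in panel.columns:
            panel[col] = math.nan
    panel = panel[["case_id", *cfg.metric_columns(), "warnings", "error"]]
    return panel, summarize_panel(panel, cfg)


def summarize_panel(panel: pd.DataFrame, config: PanelConfig | None = None) -> pd.DataFrame:
    """Median / min / max / range / IQR per metric column, NaNs excluded.
    Quartiles use linear interpolation between closest ranks."""
    cfg = config or PanelConfig()
    out = []
    for col in cfg.metric_columns():
        x = panel[col].dropna().to_numpy(dtype=float)
        if len(x) == 0:
            out.append({"metric": col, "n": 0, "median": math.nan, "min": math.nan,
                        "max": math.nan, "range": math.nan, "iqr": math.nan})
            continue
        q1, q3 = np.percentile(x, [25, 75])
        out.append(
            {"metric": col, "n": len(x), "median": float(np.median(x)),
             "min": float(x.min()), "max": float(x.max()),
             "range": float(x.max() - x.min()), "iqr": float(q3 - q1)}
        )
    return pd.DataFrame(out)


def run_association(
    panel: pd.DataFrame,
    cases: pd.DataFrame,
    config: PanelConfig | None = None,
    categorical_covariates: list[str] | None = None,
    numeric_covariates: list[str] | None = None,
    time_column: str = "correction_time",
) -> dict:
    """The full association analysis on a joined panel + case table.

    Returns a dict with:

    * ``correlations`` — Spearman of every metric vs correction time,
      ranked by |rho|;
    * ``covariate_tests`` — for each categorical covariate, Mann-Whitney U
      (2 levels) or Kruskal-Wallis with Bonferroni post-hoc (>= 3 levels)
      of correction time and of every metric across levels; for each
      numeric covariate, Spearman vs correction time and vs every metric;
    * ``skipped`` — covariates skipped (single level, too-small groups),
      with reasons;
    * ``tables`` — the same content as tidy DataFrames.
    """
    cfg = config or PanelConfig()
    merged = panel.merge(cases, on="case_id", how="inner")
    if len(merged) < 3:
        raise DegenerateInputError(
            f"only {len(merged)} cases join panel and case table; need >= 3"
        )
    metric_cols = [c for c in cfg.metric_columns() if c in panel.columns]

    correlations = metric_time_correlation_table(
        panel, cases, metric_columns=metric_cols, time_column=time_column
    )

    if categorical_covariates is None:
        categorical_covariates = [
            c for c in cases.columns
            if c not in ("case_id", time_column) and not c.startswith("_")
            and not pd.api.types.is_numeric_dtype(cases[c])
        ]
    if numeric_covariates is None:
        numeric_covariates = [
            c for c in cases.columns
            if c not in ("case_id", time_column) and not c.startswith("_")
            and pd.api.types.is_numeric_dtype(cases[c])
        ]

    covariate_tests: list[AssociationResult] = []
    skipped: list[tuple[str, str]] = []
    targets = [time_column] + metric_cols
    for cov in categorical_covariates:
        levels = merged[cov].dropna().unique().tolist()
        if len(levels) < 2:
            skipped.append((cov, "fewer than 2 levels"))
            continue
        for target in targets:
            sub = merged[[cov, target]].dropna()
            grouped = {str(lv): sub.loc[sub[cov] == lv, target].to_numpy()
                       for lv in levels}
            grouped = {k: v for k, v in grouped.items() if len(v) >= 2}
            if len(grouped) < 2:
                skipped.append((cov, f"{target}: fewer than 2 usable groups"))
                continue
            try:
                if len(grouped) == 2:
                    (l1, g1), (l2, g2) = grouped.items()
                    covariate_tests.append(
                        mann_whitney_u(g1, g2, variables=(f"{target} by {cov}", l1, l2))
                    )
                else:
                    covariate_tests.extend(
                        kruskal_wallis_with_posthoc(
                            grouped, alpha=cfg.alpha, variable=f"{target} by {cov}"
                        )
                    )
            except DegenerateInputError as exc:
                skipped.append((cov, f"{target}: {exc}"))
    for cov in numeric_covariates:
        for target in targets:
            sub = merged[[cov, target]].dropna()
            if len(sub) < 3:
                skipped.append((cov, f"{target}: fewer than 3 complete pairs"))
                continue
            try:
                covariate_tests.append(
                    spearman(sub[cov].to_numpy(), sub[target].to_numpy(),
                             variables=(cov, target))
                )
            except DegenerateInputError as exc:
                skipped.append((cov, f"{target}: {exc}"))

    return {
        "correlations": correlations,
        "covariate_tests": covariate_tests,
        "skipped": skipped,
        "tables": {
            "correlations": results_to_frame(correlations),
            "covariate_tests": results_to_frame(covariate_tests),
        },
    }
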