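"""Plain-text I/O: LAT tables as CSV, reports as CSV/JSON.

The LAT table format is long-form CSV with columns ``activation_id``,
``pair_index``, ``loop``, ``lat_ms`` (ids 1-based), one row per
(activation, bipolar pair).  Round-trips are lossless to well below the
measurement noise (values are written with 12 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .activation import ALL_PAIR_INDICES, ActivationMatrix, loop_of_pair
from .localize import LocalizationResult
from .stats import LOOP_PAIRS, ProbabilityEstimate, reported_pvalue

__all__ = [
    "read_lat_csv",
    "write_lat_csv",
    "write_probability_report",
    "read_probability_report",
    "write_paths_report",
    "write_localization_report",
]


class LatFormatError(ValueError):
    """Raised for malformed LAT CSV files, naming the offending row."""


def write_lat_csv(matrix: ActivationMatrix, path) -> None:
    rows = []
    for r, aid in enumerate(matrix.activation_ids):
        for c, p in enumerate(ALL_PAIR_INDICES):
            rows.append((int(aid), p, loop_of_pair(p), matrix.lat[r, c]))
    df = pd.DataFrame(rows, columns=["activation_id", "pair_index", "loop", "lat_ms"])
    df.to_csv(path, index=False, float_format="%.12g")


def read_lat_csv(path) -> ActivationMatrix:
    df = pd.read_csv(path)
    required = {"activation_id", "pair_index", "loop", "lat_ms"}
    if not required <= set(df.columns):
        raise LatFormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    for i, row in df.iterrows():
        p = int(row["pair_index"])
        if p not in ALL_PAIR_INDICES:
            raise LatFormatError(f"{path}, row {i + 2}: unknown pair_index {p}")
        if row["loop"] != loop_of_pair(p):
            raise LatFormatError(f"{path}, row {i + 2}: loop {row['loop']!r} does not match pair {p}")
    wide = df.pivot(index="activation_id", columns="pair_index", values="lat_ms")
    if wide.isna().any().any():
        raise LatFormatError(f"{path}: incomplete table, some (activation, pair) cells are missing")
    wide = wide.reindex(columns=list(ALL_PAIR_INDICES)).sort_index()
    return ActivationMatrix(wide.to_numpy(), activation_ids=wide.index.to_numpy())


def write_probability_report(estimates: dict, path, alpha: float = 0.1) -> None:
    """CSV report for {'first': ProbabilityEstimate, 'last': ...}."""
    rows = []
    for mode, est in estimates.items():
        for loop in est.p_star:
            for j, pair in enumerate(LOOP_PAIRS[loop]):
                raw = est.p_value[loop][j]
                rows.append(
                    dict(
                        loop=loop,
                        pair_index=int(pair),
                        mode=mode,
                        p_star=est.p_star[loop][j],
                        lb=est.lb[loop][j],
                        ub=est.ub[loop][j],
                        p_value_raw=raw,
                        p_value_reported=reported_pvalue(raw),
                        significant=bool(raw < alpha),
                    )
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_probability_report(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_paths_report(paths, matched_samples, path) -> None:
    """JSON report: per source rank the 4 pair indices, per-entry stats, T*."""
    doc = []
    for pp, ms in zip(paths, matched_samples):
        doc.append(
            {
                "source_rank": pp.source_rank,
                "path": pp.as_tuple,
                "label": str(pp),
                "entry_probabilities": list(pp.entry_probabilities),
                "entry_pvalues": list(pp.entry_pvalues),
                "reused_slots": list(pp.reused_slots),
                "T_star": int(ms.T_star) if ms is not None else None,
                "matched_activation_ids": [int(a) for a in ms.activation_ids] if ms is not None else [],
            }
        )
    Path(path).write_text(json.dumps(doc, indent=2))


def write_localization_report(results: list[LocalizationResult], path, pooled: dict | None = None) -> None:
    doc = {"placements": []}
    for r in results:
        doc["placements"].append(
            {
                "path": r.path.as_tuple,
                "cv_mean_mm_per_ms": r.cv.mean_mu,
                "cv_sd_mm_per_ms": r.cv.sd_sigma_c,
                "point_estimate_mm": [float(v) for v in r.point_estimate],
                "vertex_estimate": r.vertex_estimate,
                "dispersion_mean_spread_mm": r.dispersion["mean_spread"],
                "n_replicates": len(r.fits),
            }
        )
    if pooled is not None:
        doc["pooled"] = {
            "centroid_mm": [float(v) for v in pooled["centroid"]],
            "spread_rms_mm": pooled["spread_rms"],
            "n_placements": pooled["n_placements"],
        }
        if "centroid_error" in pooled:
            doc["pooled"]["centroid_error_mm"] = pooled["centroid_error"]
    Path(path).write_text(json.dumps(doc, indent=2))
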