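"""Readers, writers and report glue.

The counts-table dialect is a long-format CSV with columns
``subject_id, group, probe, frame, time_min, counts_whole_lung,
counts_central`` where ``probe`` is ``TCSC`` or ``DTPA``, frames are
0-based, times are minutes and the whole-lung counts include the central
ROI (peripheral = whole - central). Image stacks are multi-page TIFF or
AVI. Fit reports are JSON with deterministic key ordering.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COUNTS_COLUMNS",
    "read_counts_table",
    "write_counts_table",
    "read_image_stack",
    "write_image_stack",
    "write_fit_report",
    "read_fit_report",
    "fit_report_payload",
]

COUNTS_COLUMNS = [
    "subject_id", "group", "probe", "frame", "time_min",
    "counts_whole_lung", "counts_central",
]


class CountsTableError(ValueError):
    """Malformed or incomplete counts table."""


def read_counts_table(path) -> pd.DataFrame:
    """Read and validate a counts CSV into the canonical long format.

    Raises :class:`CountsTableError` naming the offending rows or the
    missing subject/probe combinations.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise CountsTableError(f"{path.name}: missing columns {missing}")
    for col in ("frame", "time_min", "counts_whole_lung", "counts_central"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise CountsTableError(f"{path.name}: non-numeric {col!r} at line(s) {rows}")
        df[col] = pd.to_numeric(df[col])
    bad_probe = sorted(set(df["probe"]) - {"TCSC", "DTPA"})
    if bad_probe:
        raise CountsTableError(f"{path.name}: unknown probe label(s) {bad_probe}")
    incomplete = []
    for sid, sub in df.groupby("subject_id"):
        probes = set(sub["probe"])
        if probes != {"TCSC", "DTPA"}:
            incomplete.append(f"{sid} (has {sorted(probes)})")
            continue
        n_tc = (sub["probe"] == "TCSC").sum()
        n_dt = (sub["probe"] == "DTPA").sum()
        if n_tc != n_dt:
            incomplete.append(f"{sid} ({n_tc} TCSC vs {n_dt} DTPA frames)")
    if incomplete:
        raise CountsTableError(
            f"{path.name}: incomplete subject/probe pairing: " + "; ".join(incomplete)
        )
    return df.sort_values(["subject_id", "probe", "frame"]).reset_index(drop=True)


def write_counts_table(dataset: pd.DataFrame, path) -> Path:
    """Write a counts table in the canonical column order."""
    path = Path(path)
    dataset[COUNTS_COLUMNS].to_csv(path, index=False)
    return path


def read_image_stack(path) -> np.ndarray:
    """Decode a multi-page TIFF or AVI into a grayscale (F, H, W) stack."""
    from .ffca import as_grayscale_stack

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        frames = iio.imread(path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValueError(f"{path.name}: single-frame image; need a stack of >= 2 frames")
    return as_grayscale_stack(frames)


def write_image_stack(stack: np.ndarray, path) -> Path:
    """Write a (F, H, W) stack as multi-page TIFF (dtype preserved)."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")
    return path


def _fit_dict(fit) -> dict:
    return {
        "stage": fit.stage,
        "estimates": {k: fit.estimates[k] for k in fit.param_names},
        "se": {k: fit.se[k] for k in fit.param_names},
        "ci_lower": {k: fit.ci_lower[k] for k in fit.param_names},
        "ci_upper": {k: fit.ci_upper[k] for k in fit.param_names},
        "ci_level": fit.level,
        "residual_sum_squares": fit.residual_sum_squares,
        "n_points": fit.n_points,
        "n_params": fit.n_params,
        "frozen": dict(fit.frozen),
        "success": fit.success,
        "warnings": list(fit.warnings),
    }


def fit_report_payload(estimator, aic_report=None) -> dict:
    """JSON-able report for a fitted :class:`~mccpk.ClearanceEstimator`."""
    payload = {
        "structure": estimator.structure,
        "estimates": {
            "k_lt": estimator.k_lt_, "ffca": estimator.ffca_,
            "k_lb": estimator.k_lb_, "k_db": estimator.k_db_,
            "k_dl": estimator.k_dl_,
        },
        "mcc_fit": _fit_dict(estimator.mcc_fit_),
        "absorption_fit": _fit_dict(estimator.absorption_fit_),
        "aic": estimator.aic_,
        "rss": estimator.rss_,
        "n_points": estimator.n_points_,
        "k_free": estimator.k_free_,
    }
    if aic_report is not None:
        payload["structure_comparison"] = [
            {
                "structure": r.structure.name,
                "aic_total": r.aic,
                "aic_mcc": r.aic_mcc,
                "aic_absorption": r.aic_absorption,
                "rss": r.rss,
                "n_points": r.n_points,
                "k_free": r.k_free,
                "identifiability_warnings": list(r.identifiability_warnings),
            }
            for r in aic_report.results
        ]
    return payload


def write_fit_report(payload: dict, path) -> Path:
    """Serialize a report dict to JSON (sorted keys, deterministic)."""
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
    return path


def read_fit_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
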