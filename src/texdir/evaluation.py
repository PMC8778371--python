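"""Directionality scoring with the 180-degree-periodic angular error.

The error between a true direction alpha and a predicted direction beta
is acos(|cos(alpha - beta)|) expressed in degrees: symmetric, periodic
with period 180, and bounded by 90. RMSE aggregates are grouped by bar
thickness, noise standard deviation, or blur kernel size to mirror the
robustness-sweep report structure.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

#: manifest column behind each supported grouping selector
GROUP_KEYS: dict[str, str | None] = {
    "overall": None,
    "thickness": "thickness",
    "noise_std": "magnitude",
    "blur_kernel": "magnitude",
}


def angular_error(alpha, beta):
    """180-degree-periodic angular distance in degrees, in [0, 90].

    Accepts scalars or arrays (degrees); zero iff alpha == beta (mod 180).
    """
    a = np.radians(np.asarray(alpha, dtype=np.float64))
    b = np.radians(np.asarray(beta, dtype=np.float64))
    err = np.degrees(np.arccos(np.minimum(np.abs(np.cos(a - b)), 1.0)))
    return float(err) if err.ndim == 0 else err


def rmse(errors: np.ndarray) -> float:
    errors = np.asarray(errors, dtype=np.float64)
    return float(np.sqrt(np.mean(errors ** 2))) if errors.size else float("nan")


@dataclass
class RmseReport:
    """Root-mean-square angular error per group."""

    key: str
    table: pd.DataFrame  # columns: group, rmse_deg, n_tiles
    n_rejected: int = 0

    @property
    def overall(self) -> float:
        return rmse_from_table(self.table)

    def __getitem__(self, group) -> float:
        row = self.table[self.table["group"] == group]
        if row.empty:
            raise KeyError(group)
        return float(row["rmse_deg"].iloc[0])


def rmse_from_table(table: pd.DataFrame) -> float:
    if table.empty or table["n_tiles"].sum() == 0:
        return float("nan")
    total = (table["rmse_deg"] ** 2 * table["n_tiles"]).sum()
    return float(np.sqrt(total / table["n_tiles"].sum()))


def rmse_by_group(
    errors: np.ndarray,
    manifest: pd.DataFrame,
    key: str = "overall",
) -> RmseReport:
    """Group angular errors by a provenance column and report per-group RMSE.

    ``key``: 'overall', 'thickness', 'noise_std' or 'blur_kernel'. The two
    perturbation keys restrict the rows to that perturbation kind (plus the
    unperturbed rows, reported as group 0).
    """
    if key not in GROUP_KEYS:
        raise KeyError(f"unknown grouping key {key!r}; choose from {sorted(GROUP_KEYS)}")
    errors = np.asarray(errors, dtype=np.float64)
    if len(errors) != len(manifest):
        raise ValueError("errors and manifest differ in length")
    if key == "overall":
        table = pd.DataFrame(
            {"group": ["overall"], "rmse_deg": [rmse(errors)], "n_tiles": [len(errors)]})
        return RmseReport(key, table)

    df = manifest.copy()
    df["error"] = errors
    if key == "noise_std":
        df = df[df["perturbation"].isin(["none", "gaussian_noise"])]
    elif key == "blur_kernel":
        df = df[df["perturbation"].isin(["none", "mean_blur"])]
    col = GROUP_KEYS[key]
    rows = [
        {"group": g, "rmse_deg": rmse(sub["error"].to_numpy()), "n_tiles": len(sub)}
        for g, sub in df.groupby(col, sort=True)
    ]
    return RmseReport(key, pd.DataFrame(rows))


@dataclass
class MethodComparison:
    """Per-method RMSE over a shared test set, Table-4 style."""

    reports: dict[str, RmseReport]
    throughput_tiles_per_s: dict[str, float] = field(default_factory=dict)
    rejections: dict[str, int] = field(default_factory=dict)
    failures: dict[str, int] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, report in self.reports.items():
            rows.append({
                "method": name,
                "rmse_deg": report.overall,
                "n_tiles": int(report.table["n_tiles"].sum()),
                "rejected": self.rejections.get(name, 0),
                "failed": self.failures.get(name, 0),
                "tiles_per_s": self.throughput_tiles_per_s.get(name, float("nan")),
            })
        return pd.DataFrame(rows)


def compare_methods(
    detectors: Mapping[str, Callable[[np.ndarray], "object"]],
    tiles: np.ndarray,
    labels: np.ndarray,
    manifest: pd.DataFrame | None = None,
    group_key: str = "overall",
) -> MethodComparison:
    """Run several tile -> DirectionEstimate detectors over one test set.

    Rejected tiles are excluded from RMSE and counted separately; a detector
    exception on a tile is recorded and the tile skipped for that detector.
    Wall-clock throughput is logged but is hardware-dependent, never a
    correctness surface.
    """
    labels = np.asarray(labels)
    if manifest is None:
        manifest = pd.DataFrame(index=range(len(labels)))
    reports: dict[str, RmseReport] = {}
    throughput, rejections, failures = {}, {}, {}
    for name, detect in detectors.items():
        errs, keep_idx = [], []
        n_rej = n_fail = 0
        t0 = time.perf_counter()
        for i in range(len(labels)):
            try:
                est = detect(tiles[i])
            except Exception:
                n_fail += 1
                continue
            if not est.accepted:
                n_rej += 1
                continue
            errs.append(angular_error(labels[i], est.angle_deg))
            keep_idx.append(i)
        elapsed = time.perf_counter() - t0
        report = rmse_by_group(
            np.asarray(errs), manifest.iloc[keep_idx].reset_index(drop=True), group_key)
        report.n_rejected = n_rej
        reports[name] = report
        throughput[name] = len(labels) / elapsed if elapsed > 0 else float("inf")
        rejections[name], failures[name] = n_rej, n_fail
    return MethodComparison(reports, throughput, rejections, failures)
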