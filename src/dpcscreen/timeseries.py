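"""Temporality matrices and proliferation curves.

A temporality matrix is the per-field summary of all 31 morphological
features across imaging time points (features x times); 48 columns at
30-minute intervals over 0-23.5 h in the default configuration.  The
per-field summary statistic is the mean over cells.  A proliferation
curve is the per-well cell count relative to time zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssemblyError, InvalidWellError, StatisticsError
from .morphometry import FEATURE_NAMES


@dataclass
class TemporalityMatrix:
    """31 features x T time points of per-field feature means."""

    values: np.ndarray  # (31, T)
    feature_names: tuple[str, ...]
    time_points_h: np.ndarray  # (T,), strictly increasing
    well_id: str = ""
    field_index: int = 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.feature_names), columns=self.time_points_h)


@dataclass
class ProliferationCurve:
    """Relative cell count over time; ``relative_count[0] == 1``."""

    time_points_h: np.ndarray
    relative_count: np.ndarray
    well_id: str = ""


def _interp_gaps(row: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Fill NaNs by linear interpolation; edge gaps take the nearest value."""
    bad = np.isnan(row)
    if not bad.any():
        return row
    good = ~bad
    return np.interp(times, times[good], row[good])


def assemble_temporality_matrix(
    tables: Iterable[pd.DataFrame],
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> TemporalityMatrix:
    """Average cell features per time point into a features x T matrix.

    Input tables are per-time feature tables (as produced by
    :func:`dpcscreen.morphometry.extract_features`) sharing one
    well/field; input order is irrelevant (times are sorted internally).
    Time points with zero cells are filled by linear interpolation
    between their populated neighbours (nearest value at the edges).
    """
    tables = list(tables)
    if not tables:
        raise AssemblyError("need at least one feature table")
    merged = pd.concat(tables, ignore_index=True)
    if "time_h" not in merged.columns:
        raise AssemblyError("feature tables lack a time_h column")
    times = np.array(sorted({float(t) for df in tables for t in np.atleast_1d(df["time_h"].unique())}))
    if merged.empty or times.size == 0:
        raise AssemblyError("zero cells at every time point")
    means = merged.groupby("time_h")[list(feature_names)].mean()
    mat = np.full((len(feature_names), times.size), np.nan)
    for j, t in enumerate(times):
        if t in means.index:
            mat[:, j] = means.loc[t].to_numpy()
    if np.isnan(mat).all():
        raise AssemblyError("zero cells at every time point")
    for i in range(mat.shape[0]):
        mat[i] = _interp_gaps(mat[i], times)
    well = str(merged["well_id"].iloc[0]) if "well_id" in merged and len(merged) else ""
    fidx = int(merged["field_index"].iloc[0]) if "field_index" in merged and len(merged) else 1
    return TemporalityMatrix(
        values=mat,
        feature_names=tuple(feature_names),
        time_points_h=times,
        well_id=well,
        field_index=fidx,
    )


def proliferation_curve(
    counts: Sequence[float], times_h: Sequence[float] | None = None, well_id: str = ""
) -> ProliferationCurve:
    """Relative proliferation: count(t) / count(0)."""
    counts = np.asarray(counts, dtype=float)
    if times_h is None:
        times_h = np.arange(counts.size, dtype=float)
    times_h = np.asarray(times_h, dtype=float)
    order = np.argsort(times_h)
    counts, times_h = counts[order], times_h[order]
    if counts.size == 0 or counts[0] <= 0:
        raise InvalidWellError(f"well {well_id or '?'}: zero cells at time zero")
    return ProliferationCurve(
        time_points_h=times_h, relative_count=counts / counts[0], well_id=well_id
    )


def compare_count_methods(
    dpc_counts: np.ndarray,
    reference_counts: np.ndarray,
    times_h: Sequence[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-time two-sided t-test of label-free vs reference counts.

    ``dpc_counts`` and ``reference_counts`` are (n_times, n_replicates)
    arrays of aligned replicate counts.  Returns one row per time point
    with the mean difference, p-value and a "no significant difference"
    flag at the given alpha.
    """
    dpc = np.asarray(dpc_counts, dtype=float)
    ref = np.asarray(reference_counts, dtype=float)
    if dpc.shape != ref.shape:
        raise StatisticsError("count arrays must be aligned")
    if dpc.ndim != 2 or dpc.shape[1] < 2:
        raise StatisticsError("need >= 2 replicates per time point")
    rows = []
    for j, t in enumerate(times_h):
        diff = float(dpc[j].mean() - ref[j].mean())
        if np.allclose(dpc[j], ref[j]):
            p = 1.0
        else:
            p = float(stats.ttest_ind(dpc[j], ref[j]).pvalue)
            if np.isnan(p):  # zero variance in both groups but unequal means
                p = 0.0
        rows.append(
            {
                "time_h": float(t),
                "mean_difference": diff,
                "p_value": p,
                "no_significant_difference": bool(p >= alpha),
            }
        )
    return pd.DataFrame(rows)
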