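"""Plate quality control and the cumulative-distribution hit filter.

The Z' factor, ``1 - 3(sigma_m + sigma_c)/|mu_m - mu_c|``, measures the
separation between the model group (stimulated, e.g. 10 ng/mL TGF-beta)
and the control group on a plate; Z' > 0.5 is the conventional
excellent-assay threshold.  The CV, ``SD/mean x 100%``, measures
replicate dispersion.  The cumulative filter classifies compound
readouts against the empirical control and model distributions:
a *hit* is suppressed into the model group's lower tail without falling
below the control range (anti-proliferative but not cytotoxic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import QcError, StatisticsError


@dataclass(frozen=True)
class GroupStats:
    """Mean/SD/n of one reference group's readout."""

    mu: float
    sigma: float
    n: int
    readout_name: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n < 2:
            raise ValueError("need n >= 2 per group")

    @classmethod
    def from_values(cls, values, readout_name: str = "") -> "GroupStats":
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise StatisticsError("need >= 2 readouts per group")
        return cls(mu=float(v.mean()), sigma=float(v.std(ddof=1)), n=v.size, readout_name=readout_name)


@dataclass(frozen=True)
class PlateQc:
    plate_id: str
    z_prime: float
    cv_control: float
    cv_model: float
    pass_flag: bool


def z_prime(control: GroupStats, model: GroupStats) -> float:
    """Z' factor: ``1 - 3(sigma_m + sigma_c)/|mu_m - mu_c|``.

    May be negative; equals 1 only when both SDs are zero.  Equal group
    means leave the statistic undefined and raise :class:`QcError`.
    """
    gap = abs(model.mu - control.mu)
    if gap == 0:
        raise QcError("Z' undefined: model and control means are equal")
    return 1.0 - 3.0 * (model.sigma + control.sigma) / gap


def coefficient_of_variation(values) -> float:
    """CV in percent: sample SD (n-1 denominator) over the mean, x100."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise StatisticsError("need >= 2 values for a CV")
    mean = v.mean()
    if mean == 0:
        raise QcError("CV undefined: mean is zero")
    return float(v.std(ddof=1) / abs(mean) * 100.0)


def plate_qc(
    plate_id: str,
    control_readouts,
    model_readouts,
    z_prime_min: float = 0.5,
    cv_max: float | None = None,
    readout_name: str = "relative_count_24h",
) -> PlateQc:
    """Compute per-plate Z' and CVs and the pass flag (Z' > z_prime_min)."""
    ctrl = GroupStats.from_values(control_readouts, readout_name)
    model = GroupStats.from_values(model_readouts, readout_name)
    zp = z_prime(ctrl, model)
    cv_c = coefficient_of_variation(control_readouts)
    cv_m = coefficient_of_variation(model_readouts)
    ok = zp > z_prime_min
    if cv_max is not None:
        ok = ok and cv_c <= cv_max and cv_m <= cv_max
    return PlateQc(plate_id=plate_id, z_prime=zp, cv_control=cv_c, cv_model=cv_m, pass_flag=ok)


def cumulative_hit_filter(
    compound_readouts,
    control_readouts,
    model_readouts,
    control_level: float = 0.95,
    model_tail: float = 0.05,
    mode: str = "lower_tail",
) -> pd.DataFrame:
    """Classify compound readouts as hit / inactive / toxic-suspect.

    Empirical-quantile rule (type-7 interpolation): a compound is a
    *hit* when its readout is at or below the ``model_tail`` quantile of
    the model distribution while staying at or above the lower bound of
    the control group's central ``control_level`` interval; readouts
    below the control band are *toxic-suspect*; everything else is
    *inactive*.  ``mode="two_sided"`` instead requires the readout to
    fall inside the central ``model_tail`` interval of the model
    distribution (the alternative reading of the filter).
    """
    ctrl = np.asarray(control_readouts, dtype=float)
    model = np.asarray(model_readouts, dtype=float)
    if ctrl.size < 6 or model.size < 6:
        raise StatisticsError("need >= 6 control and >= 6 model reference readouts")
    if isinstance(compound_readouts, pd.Series):
        ids = list(compound_readouts.index)
        values = compound_readouts.to_numpy(dtype=float)
    else:
        values = np.asarray(compound_readouts, dtype=float)
        ids = list(range(values.size))

    lo_ctrl = float(np.quantile(ctrl, (1.0 - control_level) / 2.0))
    if mode == "lower_tail":
        in_model_window = values <= float(np.quantile(model, model_tail))
    elif mode == "two_sided":
        lo_m = float(np.quantile(model, 0.5 - model_tail / 2.0))
        hi_m = float(np.quantile(model, 0.5 + model_tail / 2.0))
        in_model_window = (values >= lo_m) & (values <= hi_m)
    else:
        raise ValueError("mode must be 'lower_tail' or 'two_sided'")

    category = np.where(
        values < lo_ctrl,
        "toxic-suspect",
        np.where(in_model_window, "hit", "inactive"),
    )
    return pd.DataFrame(
        {
            "compound_id": ids,
            "readout": values,
            "category": category,
            "hit": category == "hit",
        }
    ).set_index("compound_id")
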