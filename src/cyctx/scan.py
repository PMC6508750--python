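"""Deterministic parameter sweeps over the closed-form quantities.

A :class:`ScanSpec` declares one or more axes (kinetic-rate paths or stage
durations), a base parameter set, and the stationary outputs to tabulate.
:func:`run_scan` evaluates the closed forms at every grid point in row-major
order over the axes as declared, so re-running a spec reproduces the table
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .homeostasis import volume_growth
from .params import ConfigError, ModelParams
from .steady_state import SteadyStateSummary, constitutive_fold_change, summarize

__all__ = ["Axis", "ScanSpec", "run_scan", "duplication_time_sweep", "format_csv"]

_SUMMARY_FIELDS = tuple(SteadyStateSummary.__dataclass_fields__)
_EXTRA_OUTPUTS = ("r_v",)

#: duration pseudo-paths, interpreted as mean stage durations in minutes
_DURATION_PATHS = {"cycle.T1_min": "cycle.kappa1", "cycle.T2_min": "cycle.kappa2"}


@dataclass(frozen=True)
class Axis:
    """One scan axis: a parameter path swept over a range.

    ``path`` is a dotted rate path (``stage1.lam`` ... ``cycle.kappa2``) or
    a duration pseudo-path ``cycle.T1_min`` / ``cycle.T2_min`` (mean stage
    duration in minutes, converted internally to the rate 60/T per hour).
    ``scale`` is ``"log"`` (default, matching how stage durations are
    usually presented) or ``"linear"``.
    """

    path: str
    start: float
    stop: float
    num: int
    scale: str = "log"

    def values(self) -> np.ndarray:
        if self.num < 2:
            raise ConfigError("axis point count must be >= 2")
        if self.start <= 0 or self.stop <= 0:
            raise ConfigError("axis ranges must be positive")
        if self.scale == "log":
            return np.geomspace(self.start, self.stop, self.num)
        if self.scale == "linear":
            return np.linspace(self.start, self.stop, self.num)
        raise ConfigError(f"unknown axis scale {self.scale!r}")


@dataclass(frozen=True)
class ScanSpec:
    axes: Sequence[Axis]
    base: ModelParams
    outputs: Sequence[str] = field(default_factory=lambda: list(_SUMMARY_FIELDS))

    def __post_init__(self) -> None:
        known = set(_SUMMARY_FIELDS) | set(_EXTRA_OUTPUTS)
        unknown = [o for o in self.outputs if o not in known]
        if unknown:
            raise ConfigError(f"unknown output name(s) {unknown}; known: {sorted(known)}")


def _apply(params: ModelParams, path: str, value: float) -> ModelParams:
    if path in _DURATION_PATHS:
        return params.replace_rate(_DURATION_PATHS[path], 60.0 / value)
    return params.replace_rate(path, value)


def run_scan(spec: ScanSpec) -> pd.DataFrame:
    """Evaluate the requested outputs over the full grid.

    Returns one row per grid point, row-major over the axes as declared,
    with the axis values in the leading columns.
    """
    axis_values = [ax.values() for ax in spec.axes]
    mesh = np.meshgrid(*axis_values, indexing="ij")
    flat = [m.ravel() for m in mesh]
    rows = []
    for point in zip(*flat):
        params = spec.base
        for ax, val in zip(spec.axes, point):
            params = _apply(params, ax.path, float(val))
        row = dict(zip((ax.path for ax in spec.axes), point))
        summary = summarize(params).as_dict()
        for name in spec.outputs:
            if name == "r_v":
                row[name] = volume_growth(params.cycle).r_v
            else:
                row[name] = summary[name]
        rows.append(row)
    return pd.DataFrame(rows)


def duplication_time_sweep(
    nu1: float,
    nu2: float,
    delta: float,
    cycle_total_min: float,
    duplication_times_min: Sequence[float],
) -> pd.DataFrame:
    """Constitutive-limit stage means and fold change vs duplication timing.

    The cell-cycle length is held fixed at ``cycle_total_min`` while the
    gene-duplication time ``t_dup`` moves through it, so
    ``kappa1 = 1/t_dup`` and ``kappa2 = 1/(cycle_total - t_dup)`` (per
    minute).  Synthesis rates are per minute; ``delta`` is per hour (the
    usual mixed presentation) and is converted internally.
    """
    rows = []
    delta_per_min = delta / 60.0
    for t_dup in duplication_times_min:
        if not 0.0 < t_dup < cycle_total_min:
            raise ConfigError(
                f"duplication time {t_dup!r} outside (0, {cycle_total_min}) min"
            )
        k1 = 1.0 / t_dup
        k2 = 1.0 / (cycle_total_min - t_dup)
        m1, m2, r = constitutive_fold_change(nu1, nu2, delta_per_min, k1, k2)
        rows.append({"t_dup_min": t_dup, "m1_star": m1, "m2_star": m2, "r_star": r})
    return pd.DataFrame(rows)


def format_csv(df: pd.DataFrame) -> str:
    """Render a table with floats at 10 significant digits (diff-stable)."""
    return df.to_csv(index=False, float_format="%.10g")
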