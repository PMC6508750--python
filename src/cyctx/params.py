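"""Kinetic parameter containers, unit normalization and validation.

The model splits one cell division cycle into an early stage S1 (one copy of
the gene of interest, before its replication) and a late stage S2 (two
independently transcribed copies).  Each stage carries its own telegraph
kinetics -- promoter activation ``lam``, inactivation ``gamma``, mRNA
synthesis ``nu`` and degradation ``delta`` -- and the stage durations are
exponential with rates ``kappa1`` (S1 -> S2, i.e. gene duplication) and
``kappa2`` (S2 -> division).

All rates are stored internally in units of per hour.  Published parameter
sets often mix per-minute and per-hour values; :func:`normalize_units`
converts tagged inputs at the boundary (factor of exactly 60).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "StageKinetics",
    "CellCycleRates",
    "ModelParams",
    "ParameterError",
    "ConfigError",
    "normalize_units",
    "load_params",
    "mean_gene_duplication_time",
]


class ParameterError(ValueError):
    """A kinetic rate violates the model's positivity/finiteness contract."""


class ConfigError(ValueError):
    """A configuration file or mapping could not be interpreted."""


def _check_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ParameterError(f"{name} must be strictly positive and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class StageKinetics:
    """Telegraph rates of one cell-cycle stage, in per-hour units.

    Attributes
    ----------
    lam : float
        Promoter activation rate (OFF -> ON), per gene copy.
    gamma : float
        Promoter inactivation rate (ON -> OFF), per active copy.
    nu : float
        mRNA synthesis rate per active gene copy.
    delta : float
        First-order mRNA degradation rate.
    """

    lam: float
    gamma: float
    nu: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("lam", "gamma", "nu", "delta"):
            object.__setattr__(self, name, _check_positive(name, getattr(self, name)))


@dataclass(frozen=True)
class CellCycleRates:
    """Exponential stage-transition rates, per hour.

    ``kappa1`` takes the cell from S1 to S2 (instantaneous gene duplication);
    ``kappa2`` takes it from S2 through division back to S1.
    """

    kappa1: float
    kappa2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kappa1", _check_positive("kappa1", self.kappa1))
        object.__setattr__(self, "kappa2", _check_positive("kappa2", self.kappa2))

    @property
    def stage_weights(self) -> tuple[float, float]:
        """Stationary occupancy (P1, P2) of the two stages."""
        tot = self.kappa1 + self.kappa2
        return self.kappa2 / tot, self.kappa1 / tot

    @classmethod
    def from_durations_hours(cls, t1: float, t2: float) -> "CellCycleRates":
        """Build from mean stage durations in hours (kappa = 1/duration)."""
        return cls(1.0 / _check_positive("T1", t1), 1.0 / _check_positive("T2", t2))


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: two stage kinetics plus cycle transition rates."""

    stage1: StageKinetics
    stage2: StageKinetics
    cycle: CellCycleRates

    def __post_init__(self) -> None:
        # These combinations appear as denominators of the stationary first
        # and second moments.  Positivity follows from rate positivity
        # (2ab > kappa1*kappa2 when a > kappa1, b > kappa2); assert anyway.
        d1, d2 = self.stage1.delta, self.stage2.delta
        k1, k2 = self.cycle.kappa1, self.cycle.kappa2
        den1 = 2.0 * (d1 + k1) * (d2 + k2) - k1 * k2
        den2 = 4.0 * (k1 + 2.0 * d1) * (k2 + 2.0 * d2) - k1 * k2
        if den1 <= 0.0 or den2 <= 0.0:
            raise ParameterError(
                "degenerate parameter set: moment denominators must be positive "
                f"(got {den1!r} and {den2!r})"
            )

    @classmethod
    def shared(cls, kinetics: StageKinetics, cycle: CellCycleRates) -> "ModelParams":
        """Same telegraph kinetics in both stages (the bacterial-like case)."""
        return cls(stage1=kinetics, stage2=kinetics, cycle=cycle)

    def replace_rate(self, path: str, value: float) -> "ModelParams":
        """Return a copy with one rate replaced.

        ``path`` is dotted, e.g. ``"stage2.lam"`` or ``"cycle.kappa1"``.
        """
        group, _, field = path.partition(".")
        if group not in ("stage1", "stage2", "cycle") or not field:
            raise ConfigError(f"unknown parameter path {path!r}")
        obj = getattr(self, group)
        if not hasattr(obj, field):
            raise ConfigError(f"unknown parameter path {path!r}")
        kwargs = {f: getattr(obj, f) for f in obj.__dataclass_fields__}
        kwargs[field] = value
        new_obj = type(obj)(**kwargs)
        parts = {"stage1": self.stage1, "stage2": self.stage2, "cycle": self.cycle}
        parts[group] = new_obj
        return ModelParams(**parts)

    def rate(self, path: str) -> float:
        group, _, field = path.partition(".")
        try:
            return float(getattr(getattr(self, group), field))
        except AttributeError as exc:
            raise ConfigError(f"unknown parameter path {path!r}") from exc


# ---------------------------------------------------------------------------
# Unit handling

_UNIT_ALIASES = {
    "per_hour": 1.0,
    "per_hr": 1.0,
    "1/hr": 1.0,
    "hr-1": 1.0,
    "/hr": 1.0,
    "per_minute": 60.0,
    "per_min": 60.0,
    "1/min": 60.0,
    "min-1": 60.0,
    "/min": 60.0,
}


def _unit_factor(tag: str, field: str) -> float:
    try:
        return _UNIT_ALIASES[str(tag).strip().lower()]
    except KeyError:
        raise ConfigError(
            f"unknown unit tag {tag!r} for field {field!r}; "
            f"recognized tags: {sorted(set(_UNIT_ALIASES))}"
        ) from None


_STAGE_KEYS = {"lambda": "lam", "lam": "lam", "gamma": "gamma", "nu": "nu", "delta": "delta"}


def _coerce_rate(field: str, raw, default_factor: float) -> float:
    """Accept a bare number, a ``[value, unit]`` pair or ``{value, unit}``."""
    if isinstance(raw, Mapping):
        if "value" not in raw:
            raise ConfigError(f"field {field!r}: mapping form requires a 'value' key")
        factor = _unit_factor(raw.get("unit", "per_hour"), field)
        return float(raw["value"]) * factor
    if isinstance(raw, (list, tuple)):
        if len(raw) != 2:
            raise ConfigError(f"field {field!r}: expected [value, unit] pair")
        return float(raw[0]) * _unit_factor(raw[1], field)
    return float(raw) * default_factor


def normalize_units(raw: Mapping) -> ModelParams:
    """Build :class:`ModelParams` from a config mapping, converting to per-hour.

    Expected keys: ``stage1`` and ``stage2`` (each with ``lambda``, ``gamma``,
    ``nu``, ``delta``), ``cycle`` (``kappa1``, ``kappa2``), and an optional
    ``units: {rates: per_hour|per_minute}`` default that applies to all bare
    numbers.  Individual rates may override the default with a
    ``{value: .., unit: ..}`` mapping or a ``[value, unit]`` pair.
    """
    units = raw.get("units", {}) or {}
    default_factor = _unit_factor(units.get("rates", "per_hour"), "units.rates")

    stages = {}
    for key in ("stage1", "stage2"):
        if key not in raw:
            raise ConfigError(f"missing required section {key!r}")
        section = raw[key]
        kwargs = {}
        for cfg_name, attr in _STAGE_KEYS.items():
            if cfg_name in section:
                kwargs[attr] = _coerce_rate(f"{key}.{cfg_name}", section[cfg_name], default_factor)
        missing = {"lam", "gamma", "nu", "delta"} - set(kwargs)
        if missing:
            raise ConfigError(f"section {key!r} missing rates: {sorted(missing)}")
        stages[key] = StageKinetics(**kwargs)

    if "cycle" not in raw:
        raise ConfigError("missing required section 'cycle'")
    cyc = raw["cycle"]
    kappas = {}
    for name in ("kappa1", "kappa2"):
        if name not in cyc:
            raise ConfigError(f"section 'cycle' missing rate {name!r}")
        kappas[name] = _coerce_rate(f"cycle.{name}", cyc[name], default_factor)
    return ModelParams(stage1=stages["stage1"], stage2=stages["stage2"], cycle=CellCycleRates(**kappas))


def load_params(path: str | Path) -> ModelParams:
    """Read a YAML or JSON parameter file and normalize it to per-hour rates."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path} does not contain a parameter mapping")
    return normalize_units(raw)


# ---------------------------------------------------------------------------


def mean_gene_duplication_time(genome_bp: float, n_genes: float, replication_rate: float) -> float:
    """Average duplication time of a single gene, in seconds.

    Dividing the genome length by the number of genes gives the mean gene
    footprint in base pairs; at a constant replication-fork speed
    (``replication_rate`` in bp/s) the per-gene duplication time is their
    ratio.  For the E. coli K-12 genome (4.64 Mbp, ~4375 genes) replicated at
    470 +/- 180 bp/s this evaluates to 1.63--3.66 s, which justifies treating
    gene duplication as instantaneous on cell-cycle timescales.
    """
    if genome_bp <= 0 or n_genes <= 0 or replication_rate <= 0:
        raise ParameterError("genome size, gene count and replication rate must be positive")
    return (genome_bp / n_genes) / replication_rate
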