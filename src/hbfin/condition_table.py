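"""Condition bands: crisp classification of symptom values.

Each symptom row of the bundled table carries up to three bands labeled
``a`` (individual/pathological-high condition), ``b`` (pathological-low)
and ``c`` (normal).  A band is a one-sided or two-sided interval whose
bounds may be arithmetic expressions of the patient's weight ``Wt``,
height ``L``, and the body-size factor ``Q``.  The suffix of every
symptom-condition literal in the knowledge base ("SPa", "PRb", ...) refers
to these labels.

Several printed rows have a pathological band that geometrically overlaps
the normal band (e.g. weight ``a: >20`` vs ``c: 50~80``).  The table is
kept faithful to its source; overlap between a pathological and the normal
band is resolved at evaluation time by the precedence ``a > b > c`` —
clinically, a value extreme enough to match a pathological band is not
classified as normal.  Overlap between the two pathological bands ``a``
and ``b``, or duplicated labels, is a genuine configuration error and is
rejected when the table loads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

from . import _expr
from .errors import ConfigError, MissingAttributeError, ValidationError

__all__ = [
    "ConditionBand",
    "ConditionTable",
    "PatientRecord",
    "load_condition_table",
    "bundled_condition_table",
    "evaluate_condition",
    "conditions_for_record",
]

LABELS = ("a", "b", "c")
_OPS = {"ge", "gt", "le", "lt", "range", "approx"}

#: grid of (Wt, L) pairs on which expression bounds are validated at load
_ANTHRO_GRID = [(wt, l) for wt in (40.0, 60.0, 75.0, 90.0, 110.0) for l in (150.0, 170.0, 190.0)]


@dataclass
class PatientRecord:
    """Named symptom values plus physiological attributes.

    ``values`` maps symptom acronyms (SP, DP, MAP, ...) to numbers; absent
    symptoms are *unknown*, never zero.  ``attributes`` may carry ``age``,
    ``gender``, ``height_cm``, ``weight_kg``.  ``label`` is an optional
    diagnosis class used for fitting and evaluation.
    """

    values: dict[str, float] = field(default_factory=dict)
    attributes: dict = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self):
        for name, v in self.values.items():
            if not math.isfinite(float(v)):
                raise ValidationError(f"symptom {name!r} has non-finite value {v!r}")

    def anthropometrics(self) -> dict[str, float]:
        """Environment for evaluating expression bounds (Wt, L, Q when known)."""
        env: dict[str, float] = {}
        wt = self.attributes.get("weight_kg", self.values.get("Wt"))
        ht = self.attributes.get("height_cm", self.values.get("L"))
        if wt is not None:
            env["Wt"] = float(wt)
        if ht is not None:
            env["L"] = float(ht)
        if "Wt" in env and "L" in env:
            env["Q"] = 0.0061 * env["L"] + 0.0128 * env["Wt"] - 0.1592
        return env


@dataclass(frozen=True)
class ConditionBand:
    """One labeled interval of one symptom row."""

    symptom: str
    label: str
    op: str
    value: float | str | None = None
    lo: float | str | None = None
    hi: float | str | None = None
    approx_tol: float = 0.10

    def _resolve(self, bound, env: Mapping[str, float]) -> float:
        if isinstance(bound, str):
            needed = _expr.variables(bound)
            unknown = needed - {"Wt", "L", "Q"}
            if unknown:
                raise ConfigError(
                    f"band {self.symptom}/{self.label}: unknown variable(s) "
                    f"{sorted(unknown)} in expression {bound!r}"
                )
            missing = needed - set(env)
            if missing:
                raise MissingAttributeError(
                    f"band {self.symptom}/{self.label} needs attribute(s) "
                    f"{sorted(missing)} to evaluate {bound!r}"
                )
            return _expr.evaluate(bound, env)
        return float(bound)

    def interval(self, env: Mapping[str, float]) -> tuple[float, float, bool, bool]:
        """(lower, upper, lower_inclusive, upper_inclusive); open sides are ±inf."""
        if self.op == "ge":
            return self._resolve(self.value, env), math.inf, True, True
        if self.op == "gt":
            return self._resolve(self.value, env), math.inf, False, True
        if self.op == "le":
            return -math.inf, self._resolve(self.value, env), True, True
        if self.op == "lt":
            return -math.inf, self._resolve(self.value, env), True, False
        if self.op == "range":
            return self._resolve(self.lo, env), self._resolve(self.hi, env), True, True
        if self.op == "approx":
            center = self._resolve(self.value, env)
            lo, hi = sorted((center * (1 - self.approx_tol), center * (1 + self.approx_tol)))
            return lo, hi, True, True
        raise ConfigError(f"band {self.symptom}/{self.label}: unknown op {self.op!r}")

    def contains(self, x: float, env: Mapping[str, float]) -> bool:
        lo, hi, lo_inc, hi_inc = self.interval(env)
        above = x >= lo if lo_inc else x > lo
        below = x <= hi if hi_inc else x < hi
        return above and below


def _overlap(i1, i2) -> bool:
    lo1, hi1, lo1i, hi1i = i1
    lo2, hi2, lo2i, hi2i = i2
    if hi1 < lo2 or hi2 < lo1:
        return False
    if hi1 == lo2:
        return hi1i and lo2i
    if hi2 == lo1:
        return hi2i and lo1i
    return True


class ConditionTable:
    """A validated set of condition bands keyed by (symptom, label)."""

    def __init__(self, bands: list[ConditionBand]):
        self._rows: dict[str, dict[str, ConditionBand]] = {}
        for band in bands:
            row = self._rows.setdefault(band.symptom, {})
            if band.label in row:
                raise ConfigError(f"duplicate band {band.symptom}/{band.label}")
            row[band.label] = band
        self.overlaps: list[tuple[str, str, str]] = []
        self._validate()

    @property
    def symptoms(self) -> list[str]:
        return sorted(self._rows)

    def bands_for(self, symptom: str) -> dict[str, ConditionBand]:
        if symptom not in self._rows:
            raise ConfigError(f"symptom {symptom!r} not in condition table")
        return self._rows[symptom]

    def _validate(self) -> None:
        for symptom, row in self._rows.items():
            for band in row.values():
                for wt, l in _ANTHRO_GRID:
                    env = {"Wt": wt, "L": l, "Q": 0.0061 * l + 0.0128 * wt - 0.1592}
                    lo, hi, *_ = band.interval(env)
                    if not (math.isfinite(lo) or math.isfinite(hi)):
                        raise ConfigError(f"band {symptom}/{band.label} is unbounded on both sides")
                    if lo > hi:
                        raise ConfigError(
                            f"band {symptom}/{band.label}: lower bound {lo:g} exceeds "
                            f"upper bound {hi:g} (Wt={wt:g}, L={l:g})"
                        )
            # a/b are both pathological: any overlap is a configuration error;
            # a/c and b/c overlaps are recorded and resolved by precedence.
            for l1, l2 in (("a", "b"), ("a", "c"), ("b", "c")):
                if l1 in row and l2 in row:
                    for wt, l in _ANTHRO_GRID:
                        env = {"Wt": wt, "L": l, "Q": 0.0061 * l + 0.0128 * wt - 0.1592}
                        if _overlap(row[l1].interval(env), row[l2].interval(env)):
                            if l2 == "c":
                                key = (symptom, l1, l2)
                                if key not in self.overlaps:
                                    self.overlaps.append(key)
                            else:
                                raise ConfigError(
                                    f"pathological bands {symptom}/{l1} and {symptom}/{l2} "
                                    f"overlap (Wt={wt:g}, L={l:g})"
                                )

    def evaluate(self, symptom: str, value: float, attributes: Mapping[str, float] | None = None) -> str | None:
        """Label of the band containing *value*, or None.

        Bands are tried in precedence order a, b, c.  Expression bounds are
        evaluated against *attributes* (Wt/L/Q; Q is derived when absent).
        """
        row = self.bands_for(symptom)
        env = dict(attributes or {})
        if "Q" not in env and "Wt" in env and "L" in env:
            env["Q"] = 0.0061 * env["L"] + 0.0128 * env["Wt"] - 0.1592
        for label in LABELS:
            band = row.get(label)
            if band is not None and band.contains(float(value), env):
                return label
        return None

    def conditions_for_record(self, record: PatientRecord) -> dict[str, str]:
        """Batch classification: one label per symptom present in record and table.

        Symptoms absent from the record, symptoms matching no band, and
        symptoms whose anthropometric bounds cannot be evaluated for this
        record are omitted (evidence unknown).
        """
        env = record.anthropometrics()
        out: dict[str, str] = {}
        for symptom, value in record.values.items():
            if symptom not in self._rows:
                continue
            try:
                label = self.evaluate(symptom, value, env)
            except MissingAttributeError:
                continue
            if label is not None:
                out[symptom] = label
        return out

    def global_range(self, symptom: str, env: Mapping[str, float], width_hint: float | None = None) -> tuple[float, float]:
        """Envelope [min lower, max upper] over a symptom's bands.

        Open sides are closed using ``3 * width_hint`` beyond the opposing
        bound; used by the synthetic cohort generator's noise model.
        """
        lows, highs = [], []
        for band in self.bands_for(symptom).values():
            lo, hi, *_ = band.interval(env)
            if not math.isfinite(lo):
                if width_hint is None:
                    raise ValidationError(f"symptom {symptom!r}: open band needs a width hint")
                lo = hi - 3 * width_hint
            if not math.isfinite(hi):
                if width_hint is None:
                    raise ValidationError(f"symptom {symptom!r}: open band needs a width hint")
                hi = lo + 3 * width_hint
            lows.append(lo)
            highs.append(hi)
        return min(lows), max(highs)


def load_condition_table(config) -> ConditionTable:
    """Build a :class:`ConditionTable` from a path, YAML string, or dict."""
    if isinstance(config, (str, bytes)) or hasattr(config, "read") or hasattr(config, "__fspath__"):
        if hasattr(config, "read"):
            config = yaml.safe_load(config)
        else:
            try:
                with open(config) as fh:
                    config = yaml.safe_load(fh)
            except (FileNotFoundError, OSError):
                config = yaml.safe_load(config)
    if not isinstance(config, dict) or "bands" not in config:
        raise ConfigError("condition-table config must be a mapping with a 'bands' list")
    tol = float(config.get("approx_tol", 0.10))
    bands = []
    for i, entry in enumerate(config["bands"]):
        try:
            op = entry["op"]
            if op not in _OPS:
                raise ConfigError(f"bands[{i}]: unknown op {op!r}")
            band = ConditionBand(
                symptom=str(entry["symptom"]),
                label=str(entry["label"]),
                op=op,
                value=entry.get("value"),
                lo=entry.get("lo"),
                hi=entry.get("hi"),
                approx_tol=tol,
            )
        except KeyError as exc:
            raise ConfigError(f"bands[{i}]: missing field {exc}") from exc
        if band.label not in LABELS:
            raise ConfigError(f"bands[{i}]: label must be one of {LABELS}, got {band.label!r}")
        if op == "range" and (band.lo is None or band.hi is None):
            raise ConfigError(f"bands[{i}]: range band needs lo and hi")
        if op != "range" and band.value is None:
            raise ConfigError(f"bands[{i}]: op {op!r} needs a value")
        bands.append(band)
    return ConditionTable(bands)


def bundled_condition_table() -> ConditionTable:
    """The package's default table (16 symptom rows)."""
    text = resources.files("hbfin.data").joinpath("condition_table.yaml").read_text()
    return load_condition_table(yaml.safe_load(text))


def evaluate_condition(symptom: str, value: float, attributes=None, table: ConditionTable | None = None) -> str | None:
    """Module-level convenience over :meth:`ConditionTable.evaluate`."""
    table = table if table is not None else bundled_condition_table()
    return table.evaluate(symptom, value, attributes)


def conditions_for_record(record: PatientRecord, table: ConditionTable | None = None) -> dict[str, str]:
    table = table if table is not None else bundled_condition_table()
    return table.conditions_for_record(record)
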