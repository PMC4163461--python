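"""Synthetic labeled cohorts respecting the condition-band geometry.

No public cohort of pulse-wave hemodynamic records exists, so every stage
of the pipeline is exercised on generated data: per diagnosis class, each
symptom is drawn uniformly within a designated condition band (with
anthropometric bounds evaluated against the record's own sampled weight
and height), then optionally corrupted by resampling from the symptom's
global range (``noise_fraction``) or dropped (``missing_fraction``).
Noise-free cohorts are therefore perfectly separable by the condition
table, by construction.

Bands open on one side (e.g. "SP ≥ 160") are sampled on a finite interval
of width ``3 × width_hint`` beyond the bound; the hints are per-symptom
spreads a clinician would consider realistic for a patient cohort.

Also houses the bundled worked-example patient record (16 symptom values)
and the stratified hold-out splitter used to separate membership-function
fitting data from validation data (default 75% for fitting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .condition_table import ConditionTable, PatientRecord, bundled_condition_table
from .errors import ValidationError
from .net_builder import FunctionFormula, bundled_formulas

__all__ = [
    "CohortSpec",
    "DEFAULT_WIDTH_HINTS",
    "default_cohort_spec",
    "generate_cohort",
    "table2_fixture",
    "holdout_split",
]

#: per-symptom sampling width for bands open on one side (same units as
#: the symptom); chosen as plausible clinical spreads
DEFAULT_WIDTH_HINTS: dict[str, float] = {
    "SP": 15.0, "DP": 10.0, "MAP": 12.0, "MDP": 12.0,
    "BV": 0.5, "PR": 15.0, "Wt": 10.0,
    "SV": 12.0, "SI": 8.0, "VPE": 0.3, "CI": 0.6,
    "Y": 0.4, "Yr": 0.4, "AC": 0.3, "FEK": 0.08, "BLK": 0.02,
}

#: default diagnosis classes: the conclusion hypotheses of the bundled
#: knowledge base that depend on no anthropometry-free gaps
DEFAULT_CLASSES = ("HT", "HPT", "Low_BE", "High_BE", "Low_CPP", "High_CPP")


@dataclass
class CohortSpec:
    """Sampling plan for one synthetic cohort.

    ``classes`` maps a diagnosis name to a per-symptom rule: either a
    condition-band label ("a"/"b"/"c") or an explicit
    ``{"mean": m, "sd": s}`` distribution.  A rule of ``None`` omits the
    symptom entirely.
    """

    classes: dict[str, dict[str, str | dict | None]]
    n_per_class: int = 50
    noise_fraction: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0
    width_hints: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WIDTH_HINTS))
    height_range: tuple[float, float] = (150.0, 190.0)
    age_range: tuple[int, int] = (30, 75)

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValidationError(f"n_per_class must be >= 1, got {self.n_per_class}")
        for name, frac in (("noise_fraction", self.noise_fraction),
                           ("missing_fraction", self.missing_fraction)):
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {frac}")

    def validate_against(self, table: ConditionTable) -> None:
        for cls, rules in self.classes.items():
            for symptom, rule in rules.items():
                if rule is None or isinstance(rule, dict):
                    continue
                bands = table.bands_for(symptom)
                if rule not in bands:
                    raise ValidationError(
                        f"class {cls!r}: symptom {symptom!r} references band {rule!r} "
                        f"which does not exist in the condition table"
                    )


def _expand_symptom_bands(formula: FunctionFormula, by_consequent) -> dict[str, str]:
    """Recursively resolve a formula's literals to (symptom -> band label)."""
    out: dict[str, str] = {}
    for lit in formula.antecedents:
        if lit.kind == "symptom":
            out[lit.symptom] = lit.suffix
        else:
            out.update(_expand_symptom_bands(by_consequent[lit.name], by_consequent))
    return out


def default_cohort_spec(
    classes=DEFAULT_CLASSES,
    n_per_class: int = 50,
    noise_fraction: float = 0.0,
    missing_fraction: float = 0.0,
    seed: int = 0,
    table: ConditionTable | None = None,
    formulas: list[FunctionFormula] | None = None,
) -> CohortSpec:
    """Cohort spec derived from the bundled knowledge base.

    Each class samples the symptoms of its (recursively expanded) formula
    within their stated bands and every other table symptom within the
    normal band ``c``; symptoms lacking a ``c`` band are omitted.  A
    ``Healthy`` class (all symptoms normal) is available by including
    "Healthy" in *classes*.
    """
    table = table if table is not None else bundled_condition_table()
    formulas = formulas if formulas is not None else bundled_formulas()
    by_consequent = {f.consequent: f for f in formulas}
    spec_classes: dict[str, dict[str, str | dict | None]] = {}
    for cls in classes:
        if cls == "Healthy":
            rules: dict[str, str] = {}
        elif cls in by_consequent:
            rules = _expand_symptom_bands(by_consequent[cls], by_consequent)
        else:
            raise ValidationError(f"class {cls!r} has no defining formula in the knowledge base")
        full: dict[str, str | dict | None] = {}
        for symptom in table.symptoms:
            if symptom in rules:
                full[symptom] = rules[symptom]
            elif "c" in table.bands_for(symptom):
                full[symptom] = "c"
            else:
                full[symptom] = None
        spec_classes[cls] = full
    return CohortSpec(classes=spec_classes, n_per_class=n_per_class,
                      noise_fraction=noise_fraction, missing_fraction=missing_fraction,
                      seed=seed)


def _sample_interval(band, env, width_hint, rng) -> float:
    lo, hi, *_ = band.interval(env)
    if not math.isfinite(lo) and not math.isfinite(hi):
        raise ValidationError(f"band {band.symptom}/{band.label} is unbounded on both sides")
    if not math.isfinite(lo):
        if width_hint is None:
            raise ValidationError(
                f"band {band.symptom}/{band.label} is open below and no sampling "
                f"width is configured"
            )
        lo = hi - 3.0 * width_hint
    if not math.isfinite(hi):
        if width_hint is None:
            raise ValidationError(
                f"band {band.symptom}/{band.label} is open above and no sampling "
                f"width is configured"
            )
        hi = lo + 3.0 * width_hint
    return float(rng.uniform(lo, hi))


def generate_cohort(spec: CohortSpec, table: ConditionTable | None = None) -> list[PatientRecord]:
    """Draw the labeled cohort described by *spec*; reproducible per seed."""
    table = table if table is not None else bundled_condition_table()
    spec.validate_against(table)
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    for cls in sorted(spec.classes):
        rules = spec.classes[cls]
        for _ in range(spec.n_per_class):
            height = float(rng.uniform(*spec.height_range))
            wt_rule = rules.get("Wt", "c")
            if isinstance(wt_rule, str):
                weight = _sample_interval(table.bands_for("Wt")[wt_rule],
                                          {}, spec.width_hints.get("Wt"), rng)
            elif isinstance(wt_rule, dict):
                weight = float(rng.normal(wt_rule["mean"], wt_rule["sd"]))
            else:
                weight = float(rng.uniform(50.0, 80.0))
            env = {"Wt": weight, "L": height,
                   "Q": 0.0061 * height + 0.0128 * weight - 0.1592}
            values: dict[str, float] = {"Wt": weight}
            for symptom in sorted(rules):
                if symptom == "Wt":
                    continue
                rule = rules[symptom]
                if rule is None:
                    continue
                if isinstance(rule, dict):
                    values[symptom] = float(rng.normal(rule["mean"], rule["sd"]))
                else:
                    band = table.bands_for(symptom)[rule]
                    values[symptom] = _sample_interval(
                        band, env, spec.width_hints.get(symptom), rng)
            # corruption: resample from the symptom's global envelope, then drop
            for symptom in sorted(values):
                if symptom == "Wt":
                    continue
                if spec.noise_fraction and rng.random() < spec.noise_fraction:
                    glo, ghi = table.global_range(symptom, env,
                                                  spec.width_hints.get(symptom))
                    values[symptom] = float(rng.uniform(glo, ghi))
                if spec.missing_fraction and rng.random() < spec.missing_fraction:
                    del values[symptom]
            records.append(PatientRecord(
                values=values,
                attributes={
                    "age": int(rng.integers(spec.age_range[0], spec.age_range[1] + 1)),
                    "gender": str(rng.choice(["F", "M"])),
                    "height_cm": height,
                    "weight_kg": weight,
                },
                label=cls,
            ))
    return records


def table2_fixture() -> PatientRecord:
    """The bundled worked-example patient record (16 symptom values).

    A partial medical record of one hypertensive patient; height is not
    part of the record, so bands needing the body-size factor Q cannot be
    evaluated for it.
    """
    values = {
        "SP": 168.0, "DP": 100.0, "MAP": 130.98, "MDP": 113.09,
        "BV": 3.5212, "PR": 68.0, "Wt": 49.0, "SV": 63.81,
        "SI": 45.54, "VPE": 2.18, "CI": 2.7, "Y": 3.0,
        "Yr": 3.8, "AC": 0.66, "FEK": 0.11, "BLK": 0.197,
    }
    return PatientRecord(values=values, attributes={"weight_kg": 49.0}, label=None)


def holdout_split(
    records: list[PatientRecord],
    fit_fraction: float = 0.75,
    seed: int = 0,
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Stratified-by-class split into (fit set, test set).

    Per class, ``round(fit_fraction * n)`` records (clamped so both sides
    stay nonempty) go to the fit set.  Deterministic per seed; disjoint
    and exhaustive.
    """
    if not (0.0 < fit_fraction < 1.0):
        raise ValidationError(f"fit_fraction must lie in (0, 1), got {fit_fraction}")
    by_class: dict[str | None, list[PatientRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec)
    rng = np.random.default_rng(seed)
    fit: list[PatientRecord] = []
    test: list[PatientRecord] = []
    for label in sorted(by_class, key=str):
        group = by_class[label]
        n = len(group)
        if n < 2:
            raise ValidationError(
                f"class {label!r} has only {n} record(s); need at least 2 to split"
            )
        order = rng.permutation(n)
        n_fit = min(max(int(round(fit_fraction * n)), 1), n - 1)
        fit.extend(group[i] for i in order[:n_fit])
        test.extend(group[i] for i in order[n_fit:])
    return fit, test
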