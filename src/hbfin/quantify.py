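"""Assign statistical parameters to inference nodes.

Symptom nodes receive *dynamic* parameters from membership grades.  With
grade f = f_i(s_j) and the rule threshold (default 0.2):

- Rule 1 (f ≥ threshold): the evidence counts as present; probability = f
  and LS = α·f (α defaults to 100).  LN is left unassigned and defaults
  to 1 in the engine (the disconfirming direction is uninformative).
- Rule 2 (f < threshold): the evidence counts as absent; probability = f
  and LN = β·f (β defaults to 10).  LS defaults to 1.

Exactly one of LS/LN is ever assigned per known grade; the switch is a
step function of the grade with its jump at the threshold (inclusive on
the Rule-1 side).

Intermediate and conclusion hypothesis nodes receive *static* parameters
by the principle of indifference: absent any reason to distinguish them,
every hypothesis node without a user-pinned prior gets the same
(prior=0.02, LS=200, LN=0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .condition_table import ConditionTable, PatientRecord, bundled_condition_table
from .errors import ConfigError, DomainError, MissingAttributeError
from .fuzzy_membership import MembershipSet
from .net_builder import InferenceNet

__all__ = [
    "QuantifyConfig",
    "EvidenceState",
    "assign_symptom_params",
    "assign_poi_params",
    "quantify_record",
    "CERTAINTY_TOL",
]

#: grades within this tolerance of 0 or 1 count as certain
CERTAINTY_TOL = 1e-9


@dataclass(frozen=True)
class QuantifyConfig:
    """Scaling constants for Rules 1-2 and the principle-of-indifference set.

    ``symptom_prior`` is the baseline probability P(x) a symptom node
    contributes to the uncertain-evidence interpolation — the belief level
    at which the evidence neither supports nor opposes a hypothesis.  It
    defaults to the rule threshold, where evidence switches from being
    categorized false to being categorized true.
    """

    alpha: float = 100.0
    beta: float = 10.0
    grade_threshold: float = 0.2
    poi_prior: float = 0.02
    poi_ls: float = 200.0
    poi_ln: float = 0.01
    symptom_prior: float | None = None

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ConfigError("alpha and beta must be zero or positive")
        if not (0.0 < self.grade_threshold < 1.0):
            raise ConfigError(f"grade_threshold must lie in (0, 1), got {self.grade_threshold}")
        if not (0.0 < self.poi_prior < 1.0):
            raise ConfigError(f"poi_prior must lie in (0, 1), got {self.poi_prior}")
        if self.poi_ls <= 0 or self.poi_ln <= 0:
            raise ConfigError("poi_ls and poi_ln must be positive")
        if self.symptom_prior is not None and not (0.0 < self.symptom_prior < 1.0):
            raise ConfigError(f"symptom_prior must lie in (0, 1), got {self.symptom_prior}")

    @property
    def effective_symptom_prior(self) -> float:
        return self.grade_threshold if self.symptom_prior is None else self.symptom_prior


@dataclass(frozen=True)
class EvidenceState:
    """Resolved evidence at one symptom node.

    ``probability`` equals the membership grade (the probability that the
    evidence holds); ``prior`` is the interpolation baseline P(x).  For a
    known grade exactly one of ``ls``/``ln`` is set; the other reads as 1
    through :meth:`ls_or_default` / :meth:`ln_or_default`.
    """

    node: str
    symptom: str | None = None
    grade: float | None = None
    probability: float | None = None
    ls: float | None = None
    ln: float | None = None
    status: str = "unknown"  # certain_true | certain_false | uncertain | unknown
    prior: float = 0.2

    def ls_or_default(self) -> float:
        return 1.0 if self.ls is None else self.ls

    def ln_or_default(self) -> float:
        return 1.0 if self.ln is None else self.ln


def _status_of(grade: float) -> str:
    if grade >= 1.0 - CERTAINTY_TOL:
        return "certain_true"
    if grade <= CERTAINTY_TOL:
        return "certain_false"
    return "uncertain"


def assign_symptom_params(
    grade: float,
    cfg: QuantifyConfig | None = None,
    *,
    node: str = "",
    symptom: str | None = None,
) -> EvidenceState:
    """Apply Rules 1-2 to a membership grade."""
    cfg = cfg or QuantifyConfig()
    if not (math.isfinite(grade) and 0.0 <= grade <= 1.0):
        raise DomainError(f"membership grade must lie in [0, 1], got {grade!r}")
    common = dict(node=node, symptom=symptom, grade=float(grade), probability=float(grade),
                  status=_status_of(grade), prior=cfg.effective_symptom_prior)
    if grade >= cfg.grade_threshold:  # Rule 1, boundary inclusive
        return EvidenceState(ls=cfg.alpha * grade, **common)
    return EvidenceState(ln=cfg.beta * grade, **common)  # Rule 2


def assign_poi_params(net: InferenceNet, cfg: QuantifyConfig | None = None) -> InferenceNet:
    """Quantify every un-pinned hypothesis node by the principle of indifference.

    Mutates and returns *net*.  Symptom and logic nodes are untouched;
    user-pinned parameters are preserved.
    """
    cfg = cfg or QuantifyConfig()
    for node in net.hypothesis_nodes:
        if net.is_pinned(node):
            continue
        net.set_params(node, cfg.poi_prior, cfg.poi_ls, cfg.poi_ln)
    return net


def quantify_record(
    net: InferenceNet,
    record: PatientRecord,
    mfs: MembershipSet | None = None,
    cfg: QuantifyConfig | None = None,
    table: ConditionTable | None = None,
) -> dict[str, EvidenceState]:
    """Resolve every symptom node of *net* against one patient record.

    Grade source, per node: the node's membership function when the set
    holds one for any consuming hypothesis (lexicographically first
    consumer wins for shared nodes); otherwise the crisp condition-band
    fallback — grade 1.0 when the record's value falls in the node's band,
    else 0.0.  Symptoms absent from the record, or whose anthropometric
    bands cannot be evaluated, are marked unknown.

    Hypothesis nodes missing parameters are quantified by the principle of
    indifference on the way.  Returns the node -> :class:`EvidenceState`
    map ready for propagation.
    """
    cfg = cfg or QuantifyConfig()
    assign_poi_params(net, cfg)
    env = record.anthropometrics()
    evidence: dict[str, EvidenceState] = {}
    for node in net.symptom_nodes:
        d = net.graph.nodes[node]
        symptom, suffix = d["symptom"], d["suffix"]
        if symptom not in record.values:
            evidence[node] = EvidenceState(node=node, symptom=symptom,
                                           prior=cfg.effective_symptom_prior)
            continue
        value = record.values[symptom]
        mf = None
        if mfs is not None:
            for hyp in net.consumers(node):
                mf = mfs.get(symptom, hyp)
                if mf is not None:
                    break
        if mf is not None:
            grade = mf(value)
        else:
            tbl = table if table is not None else bundled_condition_table()
            if symptom not in tbl.symptoms:
                raise ConfigError(
                    f"symptom node {node!r} has neither a membership function "
                    f"nor a condition band"
                )
            try:
                label = tbl.evaluate(symptom, value, env)
            except MissingAttributeError:
                evidence[node] = EvidenceState(node=node, symptom=symptom,
                                               prior=cfg.effective_symptom_prior)
                continue
            grade = 1.0 if label == suffix else 0.0
        evidence[node] = assign_symptom_params(grade, cfg, node=node, symptom=symptom)
    return evidence
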