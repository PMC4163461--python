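"""Odds-likelihood Bayesian propagation through the staged net.

Each hypothesis node h with prior P(h) updates on evidence x through the
odds form of Bayes' rule:

    O(h) = P(h) / (1 − P(h))                      (prior odds)
    O(h|x) = [∏ᵢ Lᵢ] · O(h)                       (posterior odds)
    P(h|x) = O(h|x) / (1 + O(h|x))                (posterior probability)

where each likelihood Lᵢ is LS (likelihood of sufficiency) when the i-th
evidence is certainly present, LN (likelihood of necessity) when certainly
absent, and 1 when unknown.  Evidence whose belief P(x|e) lies strictly
between 0 and 1 updates by piecewise-linear interpolation through three
anchor points — (0, P(h|x′)), (P(x), P(h)), (1, P(h|x)) — where x′ denotes
evidence certainly false and P(x) is the evidence's baseline probability:

    P(x|e) <  P(x):  P(h|e) = P(h|x′) + [P(h) − P(h|x′)] / P(x) · P(x|e)
    P(x|e) ≥  P(x):  P(h|e) = P(h) + [P(h|x) − P(h)] / (1 − P(x)) · (P(x|e) − P(x))

The two branches agree at P(x|e) = P(x), so the update is continuous.

A logic node collapses its formula's antecedents into a single effective
evidence: P(x|e) is the min (conjunction) or max (disjunction) of the
antecedent probabilities, and P(x) the same min/max over the antecedent
baselines.  Evidence with unknown status is excluded; if every antecedent
is unknown, the posterior stays at the prior.  Conditional independence
of evidence is assumed throughout — likelihoods multiply, correlations
are not modeled.

The collapsed evidence then updates the consequent with that node's own
LS/LN pair, except when a hypothesis is fed by a single lone symptom, in
which case the symptom's dynamically assigned Rule-1/Rule-2 likelihoods
apply directly.  Nodes are processed in (stage, name) order so traces are
reproducible, and each trace entry carries everything needed to replay
its posterior exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import DomainError, InferenceError
from .net_builder import InferenceNet
from .quantify import CERTAINTY_TOL, EvidenceState

__all__ = [
    "TraceEntry",
    "DiagnosisResult",
    "prior_odds",
    "posterior_odds",
    "posterior_prob_certain",
    "posterior_prob_uncertain",
    "combine_conjunction",
    "combine_disjunction",
    "propagate",
    "replay_entry",
    "explain",
]


def prior_odds(p: float) -> float:
    """O = p / (1 − p); defined only on the open interval (0, 1)."""
    if not (0.0 < p < 1.0):
        raise DomainError(f"probability must lie strictly in (0, 1) for odds, got {p}")
    return p / (1.0 - p)


def posterior_odds(o: float, likelihoods: Sequence[float]) -> float:
    """O(h|x) = [∏ Lᵢ]·O; the empty product leaves the odds unchanged."""
    if o < 0:
        raise DomainError(f"odds must be nonnegative, got {o}")
    out = o
    for L in likelihoods:
        if L < 0:
            raise DomainError(f"likelihood must be nonnegative, got {L}")
        out *= L
    return out


def posterior_prob_certain(o_post: float) -> float:
    """P = O / (1 + O); inverse of :func:`prior_odds`."""
    if o_post < 0:
        raise DomainError(f"odds must be nonnegative, got {o_post}")
    if math.isinf(o_post):
        return 1.0
    return o_post / (1.0 + o_post)


def posterior_prob_uncertain(
    p_h: float,
    p_h_given_x: float,
    p_h_given_xprime: float,
    p_x: float,
    p_x_given_e: float,
) -> float:
    """Piecewise-linear update for uncertain evidence (see module docstring)."""
    for name, v in (("p_h", p_h), ("p_h_given_x", p_h_given_x),
                    ("p_h_given_xprime", p_h_given_xprime), ("p_x_given_e", p_x_given_e)):
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"{name} must lie in [0, 1], got {v}")
    if not (0.0 < p_x < 1.0):
        raise DomainError(f"p_x must lie strictly in (0, 1), got {p_x}")
    if p_x_given_e < p_x:
        return p_h_given_xprime + (p_h - p_h_given_xprime) / p_x * p_x_given_e
    return p_h + (p_h_given_x - p_h) / (1.0 - p_x) * (p_x_given_e - p_x)


def combine_conjunction(probs: Sequence[float]) -> float:
    """Conjunction inference node: P(x) = min over contributors."""
    return _combine(probs, min, "conjunction")


def combine_disjunction(probs: Sequence[float]) -> float:
    """Disjunction inference node: P(x) = max over contributors."""
    return _combine(probs, max, "disjunction")


def _combine(probs: Sequence[float], op, name: str) -> float:
    probs = list(probs)
    if not probs:
        raise DomainError(f"{name} over an empty evidence list is undefined")
    for p in probs:
        if not (0.0 <= p <= 1.0):
            raise DomainError(f"{name} operand must lie in [0, 1], got {p}")
    return op(probs)


@dataclass(frozen=True)
class TraceEntry:
    """One hypothesis node's update, sufficient to replay its posterior."""

    hypothesis: str
    stage: int
    prior: float
    ls: float
    ln: float
    p_x_given_e: float | None
    p_x: float | None
    branch: str  # "certain_true" | "certain_false" | "interp_lower" | "interp_upper" | "prior_retained"
    antecedents: tuple[tuple[str, float | None, str], ...]
    posterior: float


@dataclass
class DiagnosisResult:
    """Posterior probabilities plus the evidence trace that produced them."""

    posteriors: dict[str, float]
    trace: dict[str, TraceEntry]
    evidence: dict[str, EvidenceState] = field(default_factory=dict)

    @property
    def ranking(self) -> list[str]:
        return sorted(self.posteriors, key=lambda h: (-self.posteriors[h], h))

    def top(self, candidates: Sequence[str] | None = None) -> str:
        pool = list(candidates) if candidates is not None else list(self.posteriors)
        missing = [h for h in pool if h not in self.posteriors]
        if missing:
            raise InferenceError(f"hypotheses not in result: {missing}")
        return min(pool, key=lambda h: (-self.posteriors[h], h))


def _certain_update(prior: float, likelihood: float) -> float:
    return posterior_prob_certain(posterior_odds(prior_odds(prior), [likelihood]))


def replay_entry(entry: TraceEntry) -> float:
    """Recompute a trace entry's posterior from its recorded inputs."""
    if entry.branch == "prior_retained":
        return entry.prior
    if entry.branch == "certain_true":
        return _certain_update(entry.prior, entry.ls)
    if entry.branch == "certain_false":
        return _certain_update(entry.prior, entry.ln)
    return posterior_prob_uncertain(
        entry.prior,
        _certain_update(entry.prior, entry.ls),
        _certain_update(entry.prior, entry.ln),
        entry.p_x,
        entry.p_x_given_e,
    )


def _clamp_unit_open(p: float, eps: float = 1e-6) -> float:
    return min(max(p, eps), 1.0 - eps)


def propagate(
    net: InferenceNet,
    evidence: Mapping[str, EvidenceState],
    atol: float = CERTAINTY_TOL,
) -> DiagnosisResult:
    """Run the staged update over every hypothesis node.

    *evidence* maps symptom-node ids to resolved :class:`EvidenceState`s
    (see :func:`hbfin.quantify.quantify_record`).  Hypothesis nodes must
    be quantified beforehand.
    """
    current: dict[str, float] = {}
    baseline: dict[str, float] = {}
    resolved: dict[str, bool] = {}
    trace: dict[str, TraceEntry] = {}

    def node_prob(n: str) -> float | None:
        if net.kind(n) == "symptom":
            state = evidence.get(n)
            if state is None or state.status == "unknown":
                return None
            return state.probability
        # an intermediate hypothesis whose own evidence was all unknown
        # carries no information either
        return current[n] if resolved[n] else None

    def node_baseline(n: str) -> float:
        if net.kind(n) == "symptom":
            return evidence[n].prior
        return baseline[n]

    for hyp in sorted(net.hypothesis_nodes, key=lambda n: (net.stage(n), n)):
        prior = net.prior(hyp)
        ls, ln = net.likelihoods(hyp)
        if prior is None or ls is None or ln is None:
            raise InferenceError(f"hypothesis node {hyp!r} is not quantified")
        baseline[hyp] = prior

        logic_nodes = net.logic_inputs(hyp)
        if not logic_nodes:
            raise InferenceError(f"hypothesis node {hyp!r} has no inbound logic node")

        # expand an implicit disjunction merge node into its formula nodes
        formula_nodes: list[str] = []
        for logic in logic_nodes:
            if net.graph.nodes[logic].get("role") == "merge":
                formula_nodes.extend(net.antecedents(logic))
            else:
                formula_nodes.append(logic)
        formula_nodes.sort()

        # collapse each formula's antecedents, then (if several formulas)
        # the implicit disjunction over them
        collapsed: list[tuple[float, float]] = []
        ante_log: list[tuple[str, float | None, str]] = []
        for fnode in formula_nodes:
            children = net.antecedents(fnode)
            child_op = net.graph.nodes[fnode]["op"]
            probs, bases = [], []
            for child in children:
                p = node_prob(child)
                status = "unknown" if p is None else (
                    evidence[child].status if net.kind(child) == "symptom" else "propagated")
                ante_log.append((child, p, status))
                if p is not None:
                    probs.append(p)
                    bases.append(node_baseline(child))
            if probs:
                comb = combine_conjunction if child_op == "and" else combine_disjunction
                collapsed.append((comb(probs), comb(bases)))

        # a hypothesis fed by one lone symptom takes that symptom's
        # dynamically assigned Rule-1/Rule-2 likelihoods
        solo_symptom: str | None = None
        if len(formula_nodes) == 1:
            children = net.antecedents(formula_nodes[0])
            if len(children) == 1 and net.kind(children[0]) == "symptom" \
                    and evidence.get(children[0]) is not None \
                    and evidence[children[0]].status != "unknown":
                solo_symptom = children[0]

        if not collapsed:
            posterior = prior
            entry = TraceEntry(hyp, net.stage(hyp), prior, ls, ln, None, None,
                               "prior_retained", tuple(ante_log), posterior)
        else:
            if len(collapsed) == 1:
                p_x_e, p_x = collapsed[0]
            else:  # implicit disjunction across alternative formulas
                p_x_e = max(c[0] for c in collapsed)
                p_x = max(c[1] for c in collapsed)

            if solo_symptom is not None:
                state = evidence[solo_symptom]
                eff_ls, eff_ln = state.ls_or_default(), state.ln_or_default()
            else:
                eff_ls, eff_ln = ls, ln

            if p_x_e >= 1.0 - atol:
                posterior = _certain_update(prior, eff_ls)
                branch = "certain_true"
            elif p_x_e <= atol:
                posterior = _certain_update(prior, eff_ln)
                branch = "certain_false"
            else:
                p_x = _clamp_unit_open(p_x)
                posterior = posterior_prob_uncertain(
                    prior,
                    _certain_update(prior, eff_ls),
                    _certain_update(prior, eff_ln),
                    p_x,
                    p_x_e,
                )
                branch = "interp_lower" if p_x_e < p_x else "interp_upper"
            posterior = min(max(posterior, 0.0), 1.0)
            entry = TraceEntry(hyp, net.stage(hyp), prior, eff_ls, eff_ln,
                               p_x_e, p_x if branch.startswith("interp") else None,
                               branch, tuple(ante_log), posterior)

        current[hyp] = posterior
        resolved[hyp] = entry.branch != "prior_retained"
        trace[hyp] = entry

    return DiagnosisResult(posteriors=current, trace=trace, evidence=dict(evidence))


_BRANCH_TEXT = {
    "certain_true": "evidence certain: odds x LS",
    "certain_false": "evidence absent: odds x LN",
    "interp_lower": "uncertain evidence below baseline: interpolate toward P(h|x')",
    "interp_upper": "uncertain evidence above baseline: interpolate toward P(h|x)",
    "prior_retained": "all evidence unknown: prior retained",
}


def explain(result: DiagnosisResult, hypothesis: str, indent: str = "") -> str:
    """Human-readable traceback from a hypothesis down to its symptoms."""
    if hypothesis not in result.trace:
        raise InferenceError(f"unknown hypothesis {hypothesis!r}")
    entry = result.trace[hypothesis]
    lines = [
        f"{indent}{hypothesis} (stage {entry.stage}): prior {entry.prior:.6g} -> "
        f"posterior {entry.posterior:.6g}"
    ]
    lines.append(f"{indent}  rule: {_BRANCH_TEXT[entry.branch]}")
    if entry.branch != "prior_retained":
        lines.append(f"{indent}  LS={entry.ls:.6g} LN={entry.ln:.6g}"
                     + (f" P(x|e)={entry.p_x_given_e:.6g}" if entry.p_x_given_e is not None else "")
                     + (f" P(x)={entry.p_x:.6g}" if entry.p_x is not None else ""))
    for name, prob, status in entry.antecedents:
        if status == "propagated":
            lines.append(f"{indent}  <- {name} [intermediate hypothesis]")
            lines.append(explain(result, name, indent + "     "))
        else:
            state = result.evidence.get(name)
            shown = "unknown" if prob is None else f"{prob:.6g}"
            extra = ""
            if state is not None and state.grade is not None:
                if state.ls is not None:
                    extra = f", LS={state.ls:.6g}"
                elif state.ln is not None:
                    extra = f", LN={state.ln:.6g}"
            lines.append(f"{indent}  <- {name}: grade {shown} ({status}{extra})")
    return "\n".join(lines)
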