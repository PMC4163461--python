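"""End-to-end pipeline: fit membership functions, diagnose, evaluate.

Binds the modules into the derive → build → fit → diagnose → evaluate
flow.  Membership functions are fitted per (symptom, consuming
hypothesis): for each symptom node of the net, the consuming hypotheses
that appear as record labels supply the labeled sample, the whole cohort
the reference sample.  Nodes whose consumers carry no labels (e.g.
intermediate hypotheses no cohort class exercises) simply keep the crisp
condition-band fallback at diagnosis time.
"""

from __future__ import annotations

import pandas as pd

from .condition_table import ConditionTable, PatientRecord, bundled_condition_table
from .errors import FitError
from .fuzzy_membership import MembershipSet, fit_mf
from .inference_engine import DiagnosisResult, propagate
from .net_builder import InferenceNet
from .quantify import QuantifyConfig, quantify_record
from .synthetic_data import holdout_split

__all__ = ["fit_membership_set", "diagnose", "evaluate_cohort"]


def fit_membership_set(
    net: InferenceNet,
    records: list[PatientRecord],
    *,
    kind: str | None = None,
    bins: int | None = None,
    min_fit_count: int = 20,
) -> MembershipSet:
    """Fit one membership function per (symptom node, labeled consumer).

    Returns the set of successful fits; nodes that cannot be fitted (no
    labeled consumer, too few samples, degenerate data) are skipped and
    fall back to crisp band evaluation during diagnosis.
    """
    labels = {r.label for r in records if r.label is not None}
    mfs = MembershipSet()
    for node in net.symptom_nodes:
        symptom = net.graph.nodes[node]["symptom"]
        all_values = [r.values[symptom] for r in records if symptom in r.values]
        for hyp in net.consumers(node):
            if hyp not in labels or mfs.get(symptom, hyp) is not None:
                continue
            labeled = [r.values[symptom] for r in records
                       if r.label == hyp and symptom in r.values]
            try:
                mf = fit_mf(labeled, all_values, kind, bins,
                            symptom=symptom, hypothesis=hyp,
                            min_fit_count=min_fit_count)
            except FitError:
                continue
            mfs.add(mf)
    return mfs


def diagnose(
    net: InferenceNet,
    record: PatientRecord,
    mfs: MembershipSet | None = None,
    table: ConditionTable | None = None,
    cfg: QuantifyConfig | None = None,
) -> DiagnosisResult:
    """Quantify one record against the net and propagate."""
    evidence = quantify_record(net, record, mfs, cfg, table)
    return propagate(net, evidence)


def evaluate_cohort(
    net: InferenceNet,
    records: list[PatientRecord],
    table: ConditionTable | None = None,
    fit_fraction: float = 0.75,
    seed: int = 0,
    cfg: QuantifyConfig | None = None,
    candidates: list[str] | None = None,
    min_fit_count: int = 20,
) -> pd.DataFrame:
    """Hold-out evaluation: fit MFs on one split, diagnose the other.

    The predicted class of a test record is the top-posterior hypothesis
    among *candidates* (default: the classes present in the cohort).
    Returns a per-class accuracy table with an "overall" row; columns are
    ``n_test``, ``n_correct``, ``accuracy_pct``.
    """
    table = table if table is not None else bundled_condition_table()
    fit_set, test_set = holdout_split(records, fit_fraction, seed)
    mfs = fit_membership_set(net, fit_set, min_fit_count=min_fit_count)
    if candidates is None:
        candidates = sorted({r.label for r in records if r.label is not None})
    counts: dict[str, list[int]] = {c: [0, 0] for c in candidates}
    for rec in test_set:
        if rec.label not in counts:
            continue
        result = diagnose(net, rec, mfs, table, cfg)
        predicted = result.top(candidates)
        counts[rec.label][0] += 1
        counts[rec.label][1] += int(predicted == rec.label)
    rows = []
    total_n = total_ok = 0
    for cls in candidates:
        n, ok = counts[cls]
        total_n += n
        total_ok += ok
        rows.append({"class": cls, "n_test": n, "n_correct": ok,
                     "accuracy_pct": 100.0 * ok / n if n else float("nan")})
    rows.append({"class": "overall", "n_test": total_n, "n_correct": total_ok,
                 "accuracy_pct": 100.0 * total_ok / total_n if total_n else float("nan")})
    return pd.DataFrame(rows)
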