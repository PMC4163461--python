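"""Shared test utilities: the independent engine oracle.

The oracle recursively applies the odds-likelihood update formulas per
consequent directly on the *formula list* — a separate code path from the
staged graph traversal it is used to check.
"""

from hbfin import EvidenceState, QuantifyConfig, assign_poi_params, assign_symptom_params, build_net, propagate

POI_PRIOR, POI_LS, POI_LN = 0.02, 200.0, 0.01
SYMPTOM_BASE = 0.2


def oracle_posteriors(formulas, grades):
    """Posterior per consequent by direct hand application of the formulas."""
    by_cons = {}
    for f in formulas:
        by_cons.setdefault(f.consequent, []).append(f)
    memo = {}

    def certain(prior, L):
        o = prior / (1 - prior) * L
        return o / (1 + o)

    def post(h):
        if h in memo:
            return memo[h]
        group = by_cons[h]
        per_formula = []
        for f in group:
            vals, bases = [], []
            for lit in f.antecedents:
                if lit.kind == "symptom":
                    g = grades.get(lit.name)
                    if g is None:
                        continue
                    vals.append(g)
                    bases.append(SYMPTOM_BASE)
                else:
                    sub, sub_resolved = post(lit.name)
                    if not sub_resolved:
                        continue
                    vals.append(sub)
                    bases.append(POI_PRIOR)
            if vals:
                op = min if f.connective == "and" else max
                per_formula.append((op(vals), op(bases)))
        lone = (len(group) == 1 and len(group[0].antecedents) == 1
                and group[0].antecedents[0].kind == "symptom"
                and grades.get(group[0].antecedents[0].name) is not None)
        if lone:
            g = grades[group[0].antecedents[0].name]
            ls = 100.0 * g if g >= 0.2 else 1.0
            ln = 10.0 * g if g < 0.2 else 1.0
        else:
            ls, ln = POI_LS, POI_LN
        if not per_formula:
            memo[h] = (POI_PRIOR, False)
            return memo[h]
        pxe = max(v for v, _ in per_formula)
        px = max(b for _, b in per_formula)
        hi, lo = certain(POI_PRIOR, ls), certain(POI_PRIOR, ln)
        if pxe >= 1 - 1e-9:
            p = hi
        elif pxe <= 1e-9:
            p = lo
        elif pxe < px:
            p = lo + (POI_PRIOR - lo) / px * pxe
        else:
            p = POI_PRIOR + (hi - POI_PRIOR) / (1 - px) * (pxe - px)
        memo[h] = (p, True)
        return memo[h]

    return {h: post(h)[0] for h in by_cons}


def run_engine(formulas, grades):
    """Quantify a throwaway net with the given symptom grades and propagate."""
    net = build_net(formulas)
    assign_poi_params(net)
    cfg = QuantifyConfig()
    evidence = {}
    for node in net.symptom_nodes:
        g = grades.get(node)
        if g is None:
            evidence[node] = EvidenceState(node=node, prior=cfg.effective_symptom_prior)
        else:
            evidence[node] = assign_symptom_params(g, cfg, node=node)
    return propagate(net, evidence)
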