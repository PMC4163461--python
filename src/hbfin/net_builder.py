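"""Parse function formulas and assemble the staged inference net.

A *function formula* is a universally quantified Horn-style implication

    forall p. SPa(p) & MDPa(p) & MAPa(p) & DPa(p) -> HT(p)

whose antecedents are either symptom-condition literals (a symptom acronym
plus a band suffix ``a``/``b``/``c``) or hypothesis literals naming another
formula's consequent.  All antecedents of one formula share a connective:
``&`` (conjunction) or ``|`` (disjunction).  Unicode input (∀, ∧, ∨, ⟶, ·)
is normalized to the ASCII dialect before parsing.

:func:`build_net` turns a formula list into a directed acyclic graph with
three node kinds:

- *symptom* nodes, one per distinct (symptom, suffix), always stage 0;
- *logic* nodes, one per formula (plus an implicit disjunction node when
  several formulas share a consequent);
- *hypothesis* nodes carrying a prior probability and LS/LN likelihoods.

Stages are longest-path layers from the symptom level, so stage numbers
strictly increase along every directed path.  Construction is canonical:
the same formula set in any order yields an identical net.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources

import networkx as nx

from .errors import ConfigError, FormulaSyntaxError, NetBuildError

__all__ = [
    "Literal",
    "FunctionFormula",
    "InferenceNet",
    "parse_formula",
    "parse_knowledge_base",
    "bundled_formulas",
    "build_net",
    "bundled_net",
    "net_to_config",
    "config_to_net",
]

SUFFIXES = ("a", "b", "c")

_UNICODE_MAP = {
    "∀": "forall ",
    "·": ".",
    "⋅": ".",
    "∧": "&",
    "∨": "|",
    "⟶": "->",
    "→": "->",
    "（": "(",
    "）": ")",
}

_LITERAL_RE = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_]*)\s*\(\s*([A-Za-z_][A-Za-z0-9_]*)\s*\)\s*$")


@dataclass(frozen=True)
class Literal:
    """One antecedent or consequent symbol of a formula."""

    name: str  # full printed name, e.g. "SPa" or "Low_BV"
    kind: str  # "symptom" | "hypothesis"
    symptom: str | None = None
    suffix: str | None = None


@dataclass(frozen=True)
class FunctionFormula:
    antecedents: tuple[Literal, ...]
    connective: str  # "and" | "or"
    consequent: str

    def __post_init__(self):
        if not self.antecedents:
            raise FormulaSyntaxError("formula has an empty antecedent list")
        if self.connective not in ("and", "or"):
            raise ConfigError(f"unknown connective {self.connective!r}")
        if any(lit.name == self.consequent for lit in self.antecedents):
            raise NetBuildError(
                f"consequent {self.consequent!r} appears among its own antecedents"
            )


def _classify(name: str) -> Literal:
    # A trailing a/b/c on a multi-character token marks a symptom-condition
    # literal; anything else names a hypothesis.  Hypothesis names must
    # therefore not end in a/b/c — true of the bundled knowledge base.
    if len(name) > 1 and name[-1] in SUFFIXES:
        return Literal(name=name, kind="symptom", symptom=name[:-1], suffix=name[-1])
    return Literal(name=name, kind="hypothesis")


def _normalize(text: str) -> str:
    for src, dst in _UNICODE_MAP.items():
        text = text.replace(src, dst)
    return text.strip()


def parse_formula(text: str) -> FunctionFormula:
    """Parse one formula line of the ASCII (or Unicode) dialect."""
    line = _normalize(text)
    original = line
    m = re.match(r"forall\s+([A-Za-z_][A-Za-z0-9_]*)\s*\.\s*", line)
    if not m:
        raise FormulaSyntaxError(f"expected 'forall <var>.' prefix in {original!r}", 0)
    var = m.group(1)
    body = line[m.end():].strip()
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1].strip()
    if "->" not in body:
        raise FormulaSyntaxError(f"missing '->' in {original!r}", original.find(body))
    lhs, _, rhs = body.partition("->")
    lhs, rhs = lhs.strip(), rhs.strip()
    if not lhs:
        raise FormulaSyntaxError(f"empty antecedent list in {original!r}", 0)

    if "&" in lhs and "|" in lhs:
        raise FormulaSyntaxError(f"mixed '&' and '|' connectives in {original!r}", 0)
    connective = "or" if "|" in lhs else "and"
    sep = "|" if connective == "or" else "&"

    antecedents = []
    for part in lhs.split(sep):
        antecedents.append(_parse_literal(part, var, original))
    consequent_lit = _parse_literal(rhs, var, original)
    return FunctionFormula(
        antecedents=tuple(antecedents),
        connective=connective,
        consequent=consequent_lit.name,
    )


def _parse_literal(part: str, var: str, original: str) -> Literal:
    m = _LITERAL_RE.match(part)
    if not m:
        raise FormulaSyntaxError(f"malformed literal {part.strip()!r} in {original!r}",
                                 original.find(part.strip()))
    name, arg = m.group(1), m.group(2)
    if arg != var:
        raise FormulaSyntaxError(
            f"literal {name}({arg}) uses variable {arg!r}, expected the "
            f"quantified {var!r} in {original!r}"
        )
    return _classify(name)


def parse_knowledge_base(text: str) -> list[FunctionFormula]:
    """Parse a knowledge-base file: one formula per line, ``#`` comments."""
    formulas = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            formulas.append(parse_formula(line))
        except FormulaSyntaxError as exc:
            raise FormulaSyntaxError(f"line {lineno}: {exc}") from exc
    return formulas


def bundled_formulas() -> list[FunctionFormula]:
    text = resources.files("hbfin.data").joinpath("formulas.txt").read_text()
    return parse_knowledge_base(text)


class InferenceNet:
    """Staged DAG of symptom, logic and hypothesis nodes.

    Thin wrapper around a :class:`networkx.DiGraph`; node attributes hold
    the kind, stage and (for hypothesis nodes) prior/LS/LN parameters.
    """

    def __init__(self, graph: nx.DiGraph):
        self.graph = graph

    # -- node sets ---------------------------------------------------------
    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == kind)

    @property
    def symptom_nodes(self) -> list[str]:
        return self.nodes_of_kind("symptom")

    @property
    def hypothesis_nodes(self) -> list[str]:
        return self.nodes_of_kind("hypothesis")

    @property
    def logic_nodes(self) -> list[str]:
        return self.nodes_of_kind("logic")

    @property
    def conclusions(self) -> list[str]:
        """Hypothesis nodes with no outbound edges (net's current leaves)."""
        return sorted(n for n in self.hypothesis_nodes if self.graph.out_degree(n) == 0)

    # -- attributes --------------------------------------------------------
    def kind(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]

    def stage(self, node: str) -> int:
        return self.graph.nodes[node]["stage"]

    def prior(self, node: str) -> float | None:
        return self.graph.nodes[node].get("prior")

    def likelihoods(self, node: str) -> tuple[float | None, float | None]:
        d = self.graph.nodes[node]
        return d.get("ls"), d.get("ln")

    def set_params(self, node: str, prior: float, ls: float, ln: float, pinned: bool = False) -> None:
        if self.kind(node) != "hypothesis":
            raise ConfigError(f"node {node!r} is not a hypothesis node")
        if not (0.0 < prior < 1.0):
            raise ConfigError(f"prior for {node!r} must lie in (0, 1), got {prior}")
        if ls < 0 or ln < 0:
            raise ConfigError(f"likelihoods for {node!r} must be nonnegative")
        self.graph.nodes[node].update(prior=float(prior), ls=float(ls), ln=float(ln), pinned=pinned)

    def is_pinned(self, node: str) -> bool:
        return bool(self.graph.nodes[node].get("pinned", False))

    # -- structure helpers -------------------------------------------------
    def logic_inputs(self, hypothesis: str) -> list[str]:
        """Logic nodes feeding a hypothesis node, in canonical order."""
        return sorted(p for p in self.graph.predecessors(hypothesis)
                      if self.kind(p) == "logic")

    def antecedents(self, logic_node: str) -> list[str]:
        return sorted(self.graph.predecessors(logic_node))

    def consumers(self, node: str) -> list[str]:
        """Consequent hypotheses of the formulas a node feeds into."""
        out = set()
        for succ in self.graph.successors(node):
            if self.kind(succ) == "hypothesis":
                out.add(succ)
            else:  # logic node -> its hypothesis (possibly via an or-node)
                for succ2 in self.graph.successors(succ):
                    if self.kind(succ2) == "hypothesis":
                        out.add(succ2)
                    else:
                        out.update(s for s in self.graph.successors(succ2)
                                   if self.kind(s) == "hypothesis")
        return sorted(out)

    def copy(self) -> "InferenceNet":
        return InferenceNet(self.graph.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, InferenceNet):
            return NotImplemented
        return net_to_config(self) == net_to_config(other)


def build_net(formulas: list[FunctionFormula]) -> InferenceNet:
    """Mechanically assemble the staged net from a formula list.

    Formulas are sorted canonically first, so construction is independent
    of input order.  Raises :class:`NetBuildError` on cycles or hypothesis
    literals with no defining formula.
    """
    formulas = sorted(
        formulas,
        key=lambda f: (f.consequent, f.connective, tuple(sorted(l.name for l in f.antecedents))),
    )
    consequents = {f.consequent for f in formulas}
    by_consequent: dict[str, list[FunctionFormula]] = {}
    for f in formulas:
        by_consequent.setdefault(f.consequent, []).append(f)

    g = nx.DiGraph()
    for cons, group in by_consequent.items():
        g.add_node(cons, kind="hypothesis")
        target = cons
        if len(group) > 1:
            # alternative evidence paths combine through an implicit
            # disjunction node
            or_node = f"{cons}#or"
            g.add_node(or_node, kind="logic", op="or", consequent=cons, role="merge")
            g.add_edge(or_node, cons)
            target = or_node
        for i, f in enumerate(group):
            logic = f"{cons}#{i}"
            g.add_node(logic, kind="logic", op=f.connective, consequent=cons, role="formula")
            g.add_edge(logic, target)
            for lit in f.antecedents:
                if lit.kind == "symptom":
                    g.add_node(lit.name, kind="symptom", symptom=lit.symptom, suffix=lit.suffix)
                else:
                    if lit.name not in consequents:
                        raise NetBuildError(
                            f"hypothesis literal {lit.name!r} in the formula for "
                            f"{cons!r} has no defining formula"
                        )
                    g.add_node(lit.name, kind="hypothesis")
                g.add_edge(lit.name, logic)

    if not nx.is_directed_acyclic_graph(g):
        cycle = " -> ".join(str(u) for u, _ in nx.find_cycle(g))
        raise NetBuildError(f"formula set is cyclic: {cycle}")

    # longest-path layering; symptom nodes pinned at stage 0
    for node in nx.topological_sort(g):
        preds = list(g.predecessors(node))
        g.nodes[node]["stage"] = 0 if not preds else 1 + max(g.nodes[p]["stage"] for p in preds)
    return InferenceNet(g)


def bundled_net() -> InferenceNet:
    """Net built from the bundled knowledge base."""
    return build_net(bundled_formulas())


def net_to_config(net: InferenceNet) -> dict:
    """Lossless JSON-serializable form of a net (topology + parameters)."""
    nodes = []
    for n in sorted(net.graph.nodes):
        d = net.graph.nodes[n]
        entry = {"id": n, "kind": d["kind"], "stage": d["stage"]}
        for key in ("symptom", "suffix", "op", "consequent"):
            if key in d:
                entry[key] = d[key]
        nodes.append(entry)
    params = {}
    for n in net.hypothesis_nodes:
        d = net.graph.nodes[n]
        if d.get("prior") is not None:
            params[n] = {"prior": d["prior"], "ls": d["ls"], "ln": d["ln"],
                         "pinned": bool(d.get("pinned", False))}
    return {
        "nodes": nodes,
        "edges": sorted([u, v] for u, v in net.graph.edges),
        "params": params,
    }


def config_to_net(config: dict) -> InferenceNet:
    """Inverse of :func:`net_to_config`, with schema validation."""
    if not isinstance(config, dict):
        raise ConfigError("net config must be a mapping")
    for key in ("nodes", "edges"):
        if key not in config:
            raise ConfigError(f"net config missing {key!r} block (at $.{key})")
    g = nx.DiGraph()
    for i, entry in enumerate(config["nodes"]):
        try:
            node_id, kind, stage = entry["id"], entry["kind"], entry["stage"]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed node entry (at $.nodes[{i}]): {exc}") from exc
        if kind not in ("symptom", "logic", "hypothesis"):
            raise ConfigError(f"unknown node kind {kind!r} (at $.nodes[{i}].kind)")
        attrs = {k: entry[k] for k in ("symptom", "suffix", "op", "consequent") if k in entry}
        g.add_node(node_id, kind=kind, stage=int(stage), **attrs)
    for j, (u, v) in enumerate(config["edges"]):
        if u not in g.nodes or v not in g.nodes:
            raise ConfigError(f"edge references undefined node (at $.edges[{j}])")
        g.add_edge(u, v)
    net = InferenceNet(g)
    for n, p in config.get("params", {}).items():
        if n not in g.nodes:
            raise ConfigError(f"params reference undefined node {n!r} (at $.params.{n})")
        net.set_params(n, float(p["prior"]), float(p["ls"]), float(p["ln"]),
                       bool(p.get("pinned", False)))
    return net


def save_net(net: InferenceNet, path, provenance: dict | None = None) -> None:
    config = net_to_config(net)
    if provenance:
        config["_provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_net(path) -> InferenceNet:
    with open(path) as fh:
        config = json.load(fh)
    config.pop("_provenance", None)
    return config_to_net(config)
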