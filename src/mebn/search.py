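"""K2-style structure search with mixed-effects node models.

Given a node ordering, each node's parents are chosen from its predecessors
by greedy forward selection under a model-selection metric; every candidate
evaluation is recorded as one test.  Orderings can be enumerated exhaustively
with root nodes pinned first and sink nodes last, networks are ranked by the
global (summed) node log-likelihood, and Markov blankets are extracted from
the winning directed acyclic graphs.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cox_frailty import CoxFrailtyScorer, SurvivalData
from .gaussian_mixed import CorrelationModel, GaussianMixedScorer
from .scores import ScoreConfig, effective_n, lrt_pvalue, score_model

__all__ = [
    "NodeSpec",
    "TestRecord",
    "LevelTrace",
    "SearchTrace",
    "FittedNodeModel",
    "NetworkStructure",
    "forward_select_node",
    "enumerate_orderings",
    "learn_network",
    "markov_blanket",
    "write_edges_tsv",
    "write_dot",
    "markov_blanket_table",
]


@dataclasses.dataclass(frozen=True)
class NodeSpec:
    """One variable in the network.

    Gaussian nodes name a single data column.  Survival nodes name the
    observed-time column and carry the event-indicator column in
    ``event_col``; they can only be children (implicit sinks), since a
    censored pair (t, delta) cannot act as a regressor.
    """

    name: str
    kind: str = "gaussian"
    event_col: str | None = None
    root: bool = False
    sink: bool = False
    candidates: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("gaussian", "survival"):
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kind == "survival" and self.event_col is None:
            raise ValueError(f"survival node {self.name!r} needs an event_col")
        if self.root and self.sink:
            raise ValueError(f"node {self.name!r} cannot be both root and sink")
        if self.root and self.candidates:
            raise ValueError(f"root node {self.name!r} cannot have candidate parents")

    @property
    def is_sink(self) -> bool:
        return self.sink or self.kind == "survival"


@dataclasses.dataclass(frozen=True)
class TestRecord:
    level: int
    candidate: str
    statistic: float
    pvalue: float | None
    score: float | None
    flagged: bool


@dataclasses.dataclass
class LevelTrace:
    level: int
    tests: list[TestRecord]
    selected: str | None


@dataclasses.dataclass
class SearchTrace:
    """Per-level record of every test performed during one node's search."""

    node: str
    metric: str
    levels: list[LevelTrace] = dataclasses.field(default_factory=list)

    @property
    def n_tests(self) -> int:
        return sum(len(lv.tests) for lv in self.levels)

    @property
    def n_flags(self) -> int:
        return sum(1 for lv in self.levels for t in lv.tests if t.flagged)

    def flags_by_level(self) -> dict[int, int]:
        return {lv.level: sum(t.flagged for t in lv.tests) for lv in self.levels}

    def tests_by_level(self) -> dict[int, int]:
        return {lv.level: len(lv.tests) for lv in self.levels}

    @property
    def selected(self) -> list[str]:
        return [lv.selected for lv in self.levels if lv.selected is not None]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "node": self.node, "metric": self.metric, "level": t.level,
                "candidate": t.candidate, "statistic": t.statistic,
                "pvalue": t.pvalue, "score": t.score, "flagged": t.flagged,
                "selected": lv.selected == t.candidate,
            }
            for lv in self.levels
            for t in lv.tests
        ]
        return pd.DataFrame(rows)


@dataclasses.dataclass
class FittedNodeModel:
    """Final parent set and fitted model of a single node."""

    node: str
    parents: tuple[str, ...]
    model: object
    loglik: float
    score: float | None
    n_e: float | None


def _make_scorer(node: NodeSpec, data: pd.DataFrame, corr: CorrelationModel,
                 candidates: Sequence[str]):
    """Build the node-appropriate scorer over [intercept | candidates]."""
    if node.kind == "gaussian":
        X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float) for c in candidates])
        return GaussianMixedScorer(data[node.name].to_numpy(float), X, corr,
                                   names=("_intercept", *candidates))
    sd = SurvivalData(
        time=data[node.name].to_numpy(float),
        event=data[node.event_col].to_numpy(),
        X=np.column_stack([data[c].to_numpy(float) for c in candidates])
        if candidates else np.empty((len(data), 0)),
    )
    return CoxFrailtyScorer(sd, corr, names=tuple(candidates))


def _node_effective_n(node: NodeSpec, scorer, corr: CorrelationModel,
                      rule: str, null_model) -> float:
    if node.kind == "survival":
        # events-based sample size for survival BIC, clusters for BIC_C
        if rule == "cluster":
            return effective_n(corr, "cluster")
        return float(scorer.n_events)
    if rule in ("jones", "yang"):
        return effective_n(corr, rule, gamma2=null_model.gamma2, sigma2=null_model.sigma2)
    return effective_n(corr, rule)


def forward_select_node(
    node: NodeSpec,
    data: pd.DataFrame,
    corr: CorrelationModel,
    cfg: ScoreConfig,
    candidates: Sequence[str] | None = None,
    scorer=None,
) -> tuple[FittedNodeModel, SearchTrace]:
    """Greedy forward selection of one node's parents under ``cfg.metric``.

    Starting from the empty parent set, every remaining candidate is fitted
    and tested at each level; candidates passing the criterion (score
    improvement for BIC/AIC, p < alpha for the LRTs) are flagged, the best
    flagged candidate joins the parent set, and the search stops at the
    first level with no flag.  Ties break toward the earlier candidate.

    A ``scorer`` built over the same candidate columns may be passed in to
    share cached fits between metrics evaluated on the same data.
    """
    if candidates is None:
        candidates = list(node.candidates or ())
    candidates = list(candidates)
    trace = SearchTrace(node=node.name, metric=cfg.metric)
    info = cfg.info
    if scorer is None:
        scorer = _make_scorer(node, data, corr, candidates)

    def fit(cols: tuple[int, ...]):
        return scorer.fit(cols) if info.integrated else scorer.fit_iid(cols)

    gaussian = node.kind == "gaussian"
    base_cols: tuple[int, ...] = (0,) if gaussian else ()
    offset = 1 if gaussian else 0  # candidate j lives in design column j+offset
    current_cols = base_cols
    current = fit(current_cols)

    n_e = None
    if info.penalty == "bic":
        null_for_ne = None
        if info.ne_rule in ("jones", "yang") and node.kind == "gaussian":
            null_for_ne = scorer.fit(base_cols)  # h2 of the node's null model
        n_e = _node_effective_n(node, scorer, corr, info.ne_rule, null_for_ne or current)
    current_score = score_model(current, cfg, n_e) if info.penalty else None
    alpha_eff = cfg.alpha / max(len(candidates), 1) if cfg.bonferroni else cfg.alpha

    remaining = list(range(len(candidates)))
    level = 0
    while remaining:
        level += 1
        records: list[TestRecord] = []
        fits: dict[int, object] = {}
        for j in remaining:
            cols = current_cols + (j + offset,)
            try:
                cand = fit(cols)
            except Exception as exc:  # noqa: BLE001 - candidate-level robustness
                warnings.warn(
                    f"fit failed for candidate {candidates[j]!r} of node "
                    f"{node.name!r}: {exc}", RuntimeWarning, stacklevel=2,
                )
                continue
            fits[j] = cand
            if info.rule == "lrt":
                lrt_tol = 0.01 if node.kind == "survival" else None
                pval = lrt_pvalue(cand, current, tol=lrt_tol)
                stat = 2.0 * (cand.loglik - current.loglik)
                flagged = pval < alpha_eff
                records.append(TestRecord(level, candidates[j], stat, pval, None, flagged))
            else:
                sc = score_model(cand, cfg, n_e)
                flagged = sc < current_score
                records.append(TestRecord(level, candidates[j], sc, None, sc, flagged))
        flagged_js = [j for j, rec in zip(fits, records) if rec.flagged]
        selected = None
        if flagged_js:
            recs = {rec.candidate: rec for rec in records}
            if info.rule == "lrt":
                best = min(flagged_js, key=lambda j: (recs[candidates[j]].pvalue, j))
            else:
                best = min(flagged_js, key=lambda j: (recs[candidates[j]].score, j))
            selected = candidates[best]
            current_cols = current_cols + (best + offset,)
            current = fits[best]
            if info.penalty:
                current_score = score_model(current, cfg, n_e)
            remaining.remove(best)
        trace.levels.append(LevelTrace(level, records, selected))
        if selected is None:
            break
    parents = tuple(trace.selected)
    fitted = FittedNodeModel(
        node=node.name, parents=parents, model=current, loglik=current.loglik,
        score=current_score, n_e=n_e,
    )
    return fitted, trace


# ---------------------------------------------------------------------------
# orderings and full-network search
# ---------------------------------------------------------------------------

def enumerate_orderings(nodes: Sequence[NodeSpec], cap: int = 8):
    """All node orderings with roots first and sinks last.

    Free (non-root, non-sink) nodes are permuted exhaustively; the number of
    free nodes must not exceed ``cap``.  Deterministic: permutations follow
    the input node order lexicographically.
    """
    roots = [nd.name for nd in nodes if nd.root]
    sinks = [nd.name for nd in nodes if nd.is_sink and not nd.root]
    free = [nd.name for nd in nodes if not nd.root and nd.name not in sinks]
    if len(free) > cap:
        raise ValueError(
            f"{len(free)} free nodes exceed the ordering cap {cap}; raise the cap, "
            "declare more roots/sinks, or pass an explicit list of orderings"
        )
    for perm in itertools.permutations(free):
        yield tuple(roots) + perm + tuple(sinks)


@dataclasses.dataclass
class NetworkStructure:
    """A learned directed acyclic graph with its fitted node models."""

    ordering: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    node_models: dict[str, FittedNodeModel]
    loglik: float
    traces: dict[str, SearchTrace] = dataclasses.field(default_factory=dict)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.ordering)
        g.add_edges_from(self.edges)
        return g

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValueError("learned edge set is not acyclic")


def learn_network(
    nodes: Sequence[NodeSpec],
    data: pd.DataFrame,
    corr: CorrelationModel,
    cfg: ScoreConfig,
    top_k: int = 3,
    ordering_cap: int = 8,
    orderings: Sequence[Sequence[str]] | None = None,
) -> list[NetworkStructure]:
    """Ordering-constrained structure learning.

    For each admissible ordering, each node's candidate parents are its
    predecessors (sinks are never candidates); parents are chosen by
    :func:`forward_select_node` and networks are ranked by the global
    log-likelihood, the sum of fitted node log-likelihoods.  Returns the
    ``top_k`` networks, keeping all structures tied with the k-th.
    """
    by_name = {nd.name: nd for nd in nodes}
    if len(by_name) != len(nodes):
        raise ValueError("duplicate node names")
    if orderings is None:
        orderings = list(enumerate_orderings(nodes, cap=ordering_cap))
    sink_names = {nd.name for nd in nodes if nd.is_sink}
    # one scorer per node over all admissible candidates, shared across orderings
    scorers: dict[str, object] = {}
    all_parents: dict[str, list[str]] = {}
    for nd in nodes:
        cands = [] if nd.root else [o.name for o in nodes
                                    if o.name != nd.name and o.name not in sink_names]
        all_parents[nd.name] = cands
        scorers[nd.name] = _make_scorer(nd, data, corr, cands)

    results: list[NetworkStructure] = []
    for ordering in orderings:
        models: dict[str, FittedNodeModel] = {}
        traces: dict[str, SearchTrace] = {}
        edges: list[tuple[str, str]] = []
        total_ll = 0.0
        for pos, name in enumerate(ordering):
            nd = by_name[name]
            preceding = set(ordering[:pos])
            cands = [c for c in all_parents[name] if c in preceding]
            # scorer columns are fixed; map the ordering-specific candidate
            # subset onto the shared scorer through the full candidate list
            fitted, trace = _forward_subset(nd, scorers[name], all_parents[name],
                                            cands, corr, cfg)
            models[name] = fitted
            traces[name] = trace
            edges.extend((p, name) for p in fitted.parents)
            total_ll += fitted.loglik
        results.append(NetworkStructure(tuple(ordering), tuple(edges), models,
                                        total_ll, traces))
    results.sort(key=lambda r: -r.loglik)
    if len(results) <= top_k:
        return results
    cutoff = results[top_k - 1].loglik
    return [r for r in results if r.loglik >= cutoff - 1e-9]


def _forward_subset(node, scorer, full_candidates, subset, corr, cfg):
    """Forward selection over a subset of a shared scorer's candidates."""
    sub = list(subset)
    spec = dataclasses.replace(node, candidates=tuple(sub))
    # Reindex through a lightweight adapter around the shared scorer.
    index = {c: j for j, c in enumerate(full_candidates)}
    gaussian = node.kind == "gaussian"
    offset = 1 if gaussian else 0

    class _View:
        n_events = getattr(scorer, "n_events", None)

        @staticmethod
        def fit(cols):
            return scorer.fit(_map(cols))

        @staticmethod
        def fit_iid(cols):
            return scorer.fit_iid(_map(cols))

    def _map(cols):
        out = []
        for c in cols:
            if gaussian and c == 0:
                out.append(0)
            else:
                out.append(index[sub[c - offset]] + offset)
        return tuple(out)

    return forward_select_node(spec, None, corr, cfg, candidates=sub, scorer=_View())


def markov_blanket(net: NetworkStructure, node: str) -> set[str]:
    """Parents, children, and the children's other parents of ``node``."""
    g = net.graph()
    if node not in g:
        raise KeyError(f"unknown node {node!r}")
    blanket = set(g.predecessors(node)) | set(g.successors(node))
    for child in g.successors(node):
        blanket |= set(g.predecessors(child))
    blanket.discard(node)
    return blanket


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def write_edges_tsv(net: NetworkStructure, path) -> None:
    pd.DataFrame(net.edges, columns=["parent", "child"]).to_csv(path, sep="\t", index=False)


def write_dot(net: NetworkStructure, path) -> None:
    lines = ["digraph bn {"]
    for name in net.ordering:
        lines.append(f'  "{name}";')
    for p, c in net.edges:
        lines.append(f'  "{p}" -> "{c}";')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def markov_blanket_table(nets: Sequence[NetworkStructure]) -> pd.DataFrame:
    """One row per node, one column per network, listing Markov blankets."""
    names = nets[0].ordering
    rows = {}
    for name in names:
        rows[name] = {
            f"MB in M{k + 1}": ", ".join(sorted(markov_blanket(net, name)))
            for k, net in enumerate(nets)
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "node"
    return df
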