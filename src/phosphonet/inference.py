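"""Subnetwork inference: augmentation, path enumeration, 4-stage ILP,
diversity ensemble and consensus.

The background network is augmented with SI-to-submodule *input* edges,
submodule-to-SI *output* edges and submodule-to-constituent edges.  All
acyclic paths of at most 3 billed edges (constituent edges are free) are
enumerated from each interrogated source regulator to the submodules that
depend on it; no-phenotype submodules may be crossed mid-path via their
constituent edges, phenotype submodules appear only as termini of their own
source.

Selection is a lexicographic integer linear program over binary path,
connection, orientation, SI-edge and intermediate-node variables:

1. maximize connected (source, submodule) pairs;
2. maximize SI edges included in a valid subnetwork;
3. minimize intermediate nodes that are neither sources, submodules nor SIs;
4. maximize selected paths.

After each stage its optimum is pinned as a constraint before the next is
optimized.  Solution diversity comes from re-solving with a 5% Bernoulli
holdout of the previous solution's non-source, non-submodule nodes; paths
present in at least 75% of the ensemble form the consensus, with node/edge
confidences equal to their ensemble frequencies.  Finally, no-phenotype
submodules whose SI made it into the consensus are added back with a direct
SI-to-submodule edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .enrichment import EnrichmentResult, INPUT, OUTPUT
from .io_model import DIRECTED, Edge, InteractionNetwork, PPI
from .submodules import NO_PHENOTYPE, Submodule

logger = logging.getLogger("phosphonet")

# edge kinds in the augmented network
KIND_BACKGROUND_PPI = "ppi"
KIND_BACKGROUND_DIR = "directed"
KIND_SI_INPUT = "si-input"
KIND_SI_OUTPUT = "si-output"
KIND_CONSTITUENT = "constituent"
KIND_ADDBACK = "add-back"

_SI_KINDS = (KIND_SI_INPUT, KIND_SI_OUTPUT)


@dataclass
class AugmentedNetwork:
    base: InteractionNetwork
    submodules: dict[str, Submodule]
    sources: tuple[str, ...]
    source_of_mutant: dict[str, str]
    si_edges: list[tuple[str, str, str]]  # (si, submodule id, kind)
    constituent_edges: list[tuple[str, str]]  # (submodule id, protein)
    si_nodes: frozenset = frozenset()

    @property
    def nodes(self) -> set[str]:
        return self.base.nodes | set(self.submodules) | set(self.si_nodes)

    def role(self, node: str) -> str:
        if node in self.sources:
            return "source"
        if node in self.submodules:
            return "submodule"
        if node in self.si_nodes:
            return "shared-interactor"
        return "protein"

    def n_added_edges(self) -> int:
        return len(self.si_edges) + len(self.constituent_edges)


def augment(
    net: InteractionNetwork,
    si_results: list[EnrichmentResult],
    submodules: list[Submodule],
    sources: tuple[str, ...],
    source_of_mutant: dict[str, str],
) -> AugmentedNetwork:
    """Attach SI-submodule and submodule-constituent edges to the background.

    Submodules with no significant SI are dropped from the augmentation
    (they are unreachable and would only inflate the instance); constituent
    edges are added only for proteins present in the background network.
    """
    for s in sources:
        if s not in net.nodes:
            raise ValueError(f"source regulator {s!r} absent from network")
    by_sub: dict[str, list[EnrichmentResult]] = {}
    for r in si_results:
        by_sub.setdefault(r.submodule, []).append(r)

    subs: dict[str, Submodule] = {}
    si_edges: list[tuple[str, str, str]] = []
    constituent_edges: list[tuple[str, str]] = []
    si_nodes: set[str] = set()
    for sub in submodules:
        hits = by_sub.get(sub.id, [])
        if not hits:
            continue
        subs[sub.id] = sub
        for r in hits:
            kind = KIND_SI_INPUT if r.role == INPUT else KIND_SI_OUTPUT
            si_edges.append((r.candidate, sub.id, kind))
            si_nodes.add(r.candidate)
        for prot in sorted(sub.proteins):
            if prot in net.nodes:
                constituent_edges.append((sub.id, prot))
            else:
                logger.info("%s: constituent %s absent from network", sub.id, prot)
    return AugmentedNetwork(
        base=net,
        submodules=subs,
        sources=tuple(sources),
        source_of_mutant=dict(source_of_mutant),
        si_edges=si_edges,
        constituent_edges=constituent_edges,
        si_nodes=frozenset(si_nodes),
    )


@dataclass(frozen=True)
class PathEdge:
    u: str
    v: str  # traversal orientation u -> v
    kind: str
    billed: bool

    def canonical(self) -> tuple[str, str, str]:
        """Identity key: undirected PPI edges collapse both orientations."""
        if self.kind == KIND_BACKGROUND_PPI:
            a, b = sorted((self.u, self.v))
            return (a, b, self.kind)
        return (self.u, self.v, self.kind)

    @property
    def forward(self) -> bool:
        """For undirected edges: traversed in lexicographic order."""
        return self.u < self.v


@dataclass(frozen=True)
class Path:
    source: str
    target: str  # submodule id
    nodes: tuple[str, ...]
    edges: tuple[PathEdge, ...]

    @property
    def billed_length(self) -> int:
        return sum(1 for e in self.edges if e.billed)


def _adjacency(aug: AugmentedNetwork) -> dict[str, list[PathEdge]]:
    adj: dict[str, list[PathEdge]] = {n: [] for n in aug.nodes}
    for e in aug.base.edges:
        if e.etype == PPI:
            adj[e.a].append(PathEdge(e.a, e.b, KIND_BACKGROUND_PPI, True))
            adj[e.b].append(PathEdge(e.b, e.a, KIND_BACKGROUND_PPI, True))
        else:
            adj[e.a].append(PathEdge(e.a, e.b, KIND_BACKGROUND_DIR, True))
    for si, sub, kind in aug.si_edges:
        if kind == KIND_SI_INPUT:
            adj[si].append(PathEdge(si, sub, kind, True))
        else:
            adj[sub].append(PathEdge(sub, si, kind, True))
    for sub, prot in aug.constituent_edges:
        adj[sub].append(PathEdge(sub, prot, KIND_CONSTITUENT, False))
    return adj


def enumerate_paths(
    aug: AugmentedNetwork, max_billed: int = 3
) -> list[Path]:
    """Depth-first enumeration of all acyclic source-to-submodule paths.

    Directed edges are traversed forward only, undirected edges either way.
    Billed length (excluding submodule-to-constituent edges) is capped at
    ``max_billed``.  A path terminates at a submodule whose dependency names
    the path's source; submodules encountered mid-path must be no-phenotype
    and are exited via constituent edges only.
    """
    adj = _adjacency(aug)
    targets_of: dict[str, set[str]] = {s: set() for s in aug.sources}
    for sid, sub in aug.submodules.items():
        if sub.dependency is not None:
            src = aug.source_of_mutant.get(sub.dependency[0])
            if src in targets_of:
                targets_of[src].add(sid)

    paths: list[Path] = []

    def dfs(source, node, visited, edges, billed):
        for pe in adj[node]:
            nxt = pe.v
            if nxt in visited:
                continue
            cost = billed + (1 if pe.billed else 0)
            if cost > max_billed:
                continue
            if nxt in aug.submodules:
                sub = aug.submodules[nxt]
                if nxt in targets_of[source]:
                    paths.append(
                        Path(source, nxt, (*visited, nxt), (*edges, pe))
                    )
                    continue  # terminus; do not extend through a target
                if sub.phenotype_class != NO_PHENOTYPE:
                    continue  # other phenotype submodules never mid-path
                # cross a no-phenotype submodule via its constituent edges
                for ce in adj[nxt]:
                    if ce.kind != KIND_CONSTITUENT or ce.v in visited:
                        continue
                    dfs(
                        source, ce.v, (*visited, nxt, ce.v),
                        (*edges, pe, ce), cost,
                    )
            else:
                dfs(source, nxt, (*visited, nxt), (*edges, pe), cost)

    for source in aug.sources:
        if not targets_of[source]:
            logger.info("source %s has no dependent submodules in play", source)
        dfs(source, source, (source,), (), 0)
    return paths


@dataclass
class Solution:
    paths: tuple[Path, ...]
    nodes: frozenset
    edges: frozenset  # canonical edge keys
    connected_pairs: frozenset  # (source, submodule id)
    orientations: dict  # undirected canonical key -> bool (forward)
    objectives: tuple[int, int, int, int]  # (pairs, SI edges, intermediates, paths)


class ILPInstance:
    """Stagewise lexicographic MILP over an enumerated path catalog."""

    def __init__(self, aug: AugmentedNetwork, catalog: list[Path]):
        self.aug = aug
        self.catalog = list(catalog)
        np_ = len(self.catalog)
        self.pairs = sorted({(p.source, p.target) for p in self.catalog})
        pair_idx = {pr: i for i, pr in enumerate(self.pairs)}

        und = sorted(
            {
                e.canonical()
                for p in self.catalog
                for e in p.edges
                if e.kind == KIND_BACKGROUND_PPI
            }
        )
        self.und = und
        und_idx = {k: i for i, k in enumerate(und)}
        si = sorted(
            {
                e.canonical()
                for p in self.catalog
                for e in p.edges
                if e.kind in _SI_KINDS
            }
        )
        self.si_edge_keys = si
        si_idx = {k: i for i, k in enumerate(si)}
        protected = set(aug.sources) | set(aug.submodules) | set(aug.si_nodes)
        inter = sorted(
            {n for p in self.catalog for n in p.nodes} - protected
        )
        self.intermediates = inter
        int_idx = {n: i for i, n in enumerate(inter)}

        # variable layout: [p | c | d | x | y]
        self.off_p = 0
        self.off_c = np_
        self.off_d = self.off_c + len(self.pairs)
        self.off_x = self.off_d + len(und)
        self.off_y = self.off_x + len(si)
        self.nvar = self.off_y + len(inter)

        rows, cols, data, ub = [], [], [], []

        def add_row(entries, bound):
            r = len(ub)
            for c, v in entries:
                rows.append(r)
                cols.append(c)
                data.append(v)
            ub.append(bound)

        paths_of_pair: dict[int, list[int]] = {i: [] for i in range(len(self.pairs))}
        paths_of_si: dict[int, list[int]] = {i: [] for i in range(len(si))}
        paths_of_node: dict[int, list[int]] = {i: [] for i in range(len(inter))}

        for i, path in enumerate(self.catalog):
            pv = self.off_p + i
            j = pair_idx[(path.source, path.target)]
            paths_of_pair[j].append(i)
            add_row([(pv, 1), (self.off_c + j, -1)], 0)  # p <= c
            for e in path.edges:
                key = e.canonical()
                if e.kind == KIND_BACKGROUND_PPI:
                    dv = self.off_d + und_idx[key]
                    if e.forward:
                        add_row([(pv, 1), (dv, -1)], 0)  # p <= d
                    else:
                        add_row([(pv, 1), (dv, 1)], 1)  # p <= 1 - d
                if e.kind in _SI_KINDS:
                    xi = si_idx[key]
                    paths_of_si[xi].append(i)
                    add_row([(pv, 1), (self.off_x + xi, -1)], 0)  # p <= x
            for n in path.nodes:
                if n in int_idx:
                    yi = int_idx[n]
                    paths_of_node[yi].append(i)
                    add_row([(pv, 1), (self.off_y + yi, -1)], 0)  # p <= y

        for j, plist in paths_of_pair.items():
            add_row(
                [(self.off_c + j, 1)] + [(self.off_p + i, -1) for i in plist], 0
            )  # c <= sum p
        for xi, plist in paths_of_si.items():
            add_row(
                [(self.off_x + xi, 1)] + [(self.off_p + i, -1) for i in plist], 0
            )  # x <= sum p (no free-floating SI edges)
        for yi, plist in paths_of_node.items():
            add_row(
                [(self.off_y + yi, 1)] + [(self.off_p + i, -1) for i in plist], 0
            )  # y <= sum p

        self._A = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(ub), self.nvar)
        )
        self._b = np.array(ub, dtype=float)

        z = np.zeros(self.nvar)
        self.obj_pairs = z.copy()
        self.obj_pairs[self.off_c : self.off_d] = 1.0
        self.obj_si = z.copy()
        self.obj_si[self.off_x : self.off_y] = 1.0
        self.obj_inter = z.copy()
        self.obj_inter[self.off_y :] = 1.0
        self.obj_paths = z.copy()
        self.obj_paths[self.off_p : self.off_c] = 1.0

    def solve_stagewise(self, excluded_nodes: frozenset = frozenset()) -> Solution:
        """Solve the four lexicographic stages; optionally exclude nodes.

        ``excluded_nodes`` models the ensemble holdout: every path visiting
        an excluded node is fixed to zero for this solve.
        """
        if not self.catalog:
            return Solution((), frozenset(), frozenset(), frozenset(), {},
                            (0, 0, 0, 0))
        lb = np.zeros(self.nvar)
        ub = np.ones(self.nvar)
        if excluded_nodes:
            for i, path in enumerate(self.catalog):
                if excluded_nodes & set(path.nodes):
                    ub[self.off_p + i] = 0.0

        stage_objs = [
            (self.obj_pairs, -1.0),  # maximize
            (self.obj_si, -1.0),     # maximize
            (self.obj_inter, 1.0),   # minimize
            (self.obj_paths, -1.0),  # maximize
        ]
        pins: list[tuple[np.ndarray, float]] = []
        optima: list[int] = []
        x = np.zeros(self.nvar)
        for obj, sign in stage_objs:
            constraints = [LinearConstraint(self._A, -np.inf, self._b)]
            for vec, val in pins:
                constraints.append(LinearConstraint(vec[None, :], val, val))
            res = milp(
                c=sign * obj,
                constraints=constraints,
                integrality=np.ones(self.nvar),
                bounds=Bounds(lb, ub),
            )
            if res.status != 0:
                raise RuntimeError(
                    f"MILP stage {len(optima) + 1} failed: {res.message}"
                )
            x = np.round(res.x)
            opt = int(round(float(obj @ x)))
            optima.append(opt)
            pins.append((obj, float(opt)))

        sel = [
            self.catalog[i]
            for i in range(len(self.catalog))
            if x[self.off_p + i] > 0.5
        ]
        nodes = frozenset(n for p in sel for n in p.nodes)
        edges = frozenset(e.canonical() for p in sel for e in p.edges)
        pairs = frozenset((p.source, p.target) for p in sel)
        orients = {
            key: bool(x[self.off_d + i] > 0.5)
            for i, key in enumerate(self.und)
            if key in edges
        }
        assert len(pairs) == optima[0], "stage-1 pin violated"
        return Solution(
            paths=tuple(sel),
            nodes=nodes,
            edges=edges,
            connected_pairs=pairs,
            orientations=orients,
            objectives=tuple(optima),
        )


def run_ensemble(
    aug: AugmentedNetwork,
    catalog: list[Path],
    n: int = 1000,
    holdout: float = 0.05,
    rng: np.random.Generator | None = None,
) -> list[Solution]:
    """Diversity ensemble: re-solve with Bernoulli holdout of prior nodes.

    Iteration 1 is unrestricted; iteration t>1 holds aside, with probability
    ``holdout`` each, the non-source non-submodule nodes selected in
    solution t-1 (for that iteration only).
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    inst = ILPInstance(aug, catalog)
    protected = set(aug.sources) | set(aug.submodules)
    solutions = [inst.solve_stagewise()]
    for _ in range(1, n):
        eligible = sorted(solutions[-1].nodes - protected)
        held = frozenset(
            node for node in eligible if rng.random() < holdout
        )
        solutions.append(inst.solve_stagewise(excluded_nodes=held))
    return solutions


@dataclass
class ConsensusNetwork:
    nodes: dict  # node -> (role, confidence)
    edges: dict  # (a, b, kind) -> confidence
    paths: list  # (Path, frequency) with frequency >= threshold
    threshold: float
    n_solutions: int
    addback_submodules: list = field(default_factory=list)


def build_consensus(
    aug: AugmentedNetwork,
    solutions: list[Solution],
    threshold: float = 0.75,
) -> ConsensusNetwork:
    """Union of paths selected in >= ``threshold`` of the ensemble.

    Node and edge confidences are ensemble frequencies (fractions of
    solutions containing the element), reported for every element that
    appears in a qualifying path.
    """
    if not solutions:
        raise ValueError("need at least one solution")
    n = len(solutions)
    path_counts: dict[Path, int] = {}
    node_counts: dict[str, int] = {}
    edge_counts: dict[tuple, int] = {}
    for sol in solutions:
        for p in sol.paths:
            path_counts[p] = path_counts.get(p, 0) + 1
        for node in sol.nodes:
            node_counts[node] = node_counts.get(node, 0) + 1
        for e in sol.edges:
            edge_counts[e] = edge_counts.get(e, 0) + 1

    qualifying = sorted(
        (
            (p, c / n)
            for p, c in path_counts.items()
            if c / n >= threshold
        ),
        key=lambda t: (-t[1], t[0].source, t[0].target, t[0].nodes),
    )
    if not qualifying:
        logger.warning("no path reached the %.0f%% threshold", 100 * threshold)
    nodes: dict[str, tuple[str, float]] = {}
    edges: dict[tuple, float] = {}
    for p, _freq in qualifying:
        for node in p.nodes:
            nodes[node] = (aug.role(node), node_counts[node] / n)
        for e in p.edges:
            edges[e.canonical()] = edge_counts[e.canonical()] / n
    return ConsensusNetwork(
        nodes=nodes, edges=edges, paths=qualifying, threshold=threshold,
        n_solutions=n,
    )


def addback_no_phenotype(
    consensus: ConsensusNetwork,
    si_results: list[EnrichmentResult],
    submodules: list[Submodule],
) -> ConsensusNetwork:
    """Re-attach no-phenotype submodules whose SI is in the consensus.

    Adds the submodule node and one directed SI-to-submodule edge per SI
    already present; pre-existing confidences are untouched.  Added elements
    inherit the confidence of their anchoring SI node.
    """
    nodes = dict(consensus.nodes)
    edges = dict(consensus.edges)
    added = []
    sub_by_id = {s.id: s for s in submodules}
    for r in si_results:
        sub = sub_by_id.get(r.submodule)
        if sub is None or sub.phenotype_class != NO_PHENOTYPE:
            continue
        if r.candidate not in consensus.nodes:
            continue
        si_conf = consensus.nodes[r.candidate][1]
        if sub.id not in nodes:
            nodes[sub.id] = ("submodule", si_conf)
            added.append(sub.id)
        else:
            nodes.setdefault(sub.id, ("submodule", si_conf))
        edges.setdefault((r.candidate, sub.id, KIND_ADDBACK), si_conf)
    return ConsensusNetwork(
        nodes=nodes,
        edges=edges,
        paths=consensus.paths,
        threshold=consensus.threshold,
        n_solutions=consensus.n_solutions,
        addback_submodules=added,
    )
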