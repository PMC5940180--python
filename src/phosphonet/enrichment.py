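"""Hypergeometric enrichment: shared interactors and generic set enrichment.

The single hypergeometric implementation here backs both the per-submodule
shared-interactor (SI) test and the generic annotation-term test.  A shared
interactor is a network protein with more interaction partners inside a
submodule's constituents than expected by chance: upper-tail hypergeometric
p over (universe N = all background-network nodes, K = constituents present
in the network, n = candidate's neighbour count, k = overlap), BH-corrected
within the submodule, called at q < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import DIRECTED, InteractionNetwork
from .submodules import Submodule

logger = logging.getLogger("phosphonet")

INPUT = "input"
OUTPUT = "output"


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).  Single source of truth."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: list[float]) -> list[float]:
    if not pvals:
        return []
    return list(multipletests(pvals, method="fdr_bh")[1])


@dataclass(frozen=True)
class EnrichmentResult:
    candidate: str
    submodule: str
    universe: int
    constituents_in_network: int
    neighbor_count: int
    overlap: int
    p: float
    q: float
    role: str  # INPUT or OUTPUT

    @property
    def significant(self) -> bool:
        return self.q < 0.05


def assign_edge_role(net: InteractionNetwork, si: str, sub: Submodule) -> str:
    """Output iff *every* SI-constituent interaction is directed constituent->SI.

    Any undirected interaction, or any interaction directed SI->constituent,
    makes the SI an input (undirected edges may be unrecognized directed
    ones, so input is the permissive default).
    """
    edges = [
        e
        for prot in sub.proteins
        if prot != si
        for e in net.edges_between(si, prot)
    ]
    if not edges:
        raise ValueError(f"{si} has no edge to a constituent of {sub.id}")
    if all(e.etype == DIRECTED and e.b == si for e in edges):
        return OUTPUT
    return INPUT


def find_shared_interactors(
    net: InteractionNetwork,
    sub: Submodule,
    alpha: float = 0.05,
    min_shared: int = 2,
    neighbor_index: dict[str, set[str]] | None = None,
) -> list[EnrichmentResult]:
    """Shared interactors of one submodule at FDR < ``alpha``.

    Candidates are all network nodes with at least ``min_shared`` constituent
    neighbours (a candidate may itself be a constituent; only its
    neighbours, never itself, count toward the overlap).  Returns all tested
    candidates with BH-adjusted q; callers filter on ``significant``.
    """
    members = {p for p in sub.proteins if p in net.nodes}
    dropped = sub.proteins - members
    if dropped:
        logger.warning(
            "%s: %d constituent protein(s) absent from network", sub.id, len(dropped)
        )
    if not members:
        logger.warning("%s: no constituents in network; no SI test", sub.id)
        return []
    N = len(net.nodes)
    K = len(members)
    idx = neighbor_index if neighbor_index is not None else net.neighbor_index()
    tested: list[tuple[str, int, int, float]] = []
    for cand in sorted(net.nodes):
        nbrs = idx[cand]
        k = len(nbrs & members)
        if k < min_shared:
            continue
        n = len(nbrs)
        tested.append((cand, n, k, hypergeom_tail(k, N, K, n)))
    qvals = bh_adjust([t[3] for t in tested])
    out = []
    for (cand, n, k, p), q in zip(tested, qvals):
        role = assign_edge_role(net, cand, sub)
        out.append(EnrichmentResult(cand, sub.id, N, K, n, k, p, q, role))
    return sorted(out, key=lambda r: (r.p, r.candidate))


def find_all_shared_interactors(
    net: InteractionNetwork,
    submodules: list[Submodule],
    alpha: float = 0.05,
    min_shared: int = 2,
    bh_scope: str = "per-submodule",
) -> list[EnrichmentResult]:
    """SI calls across submodules; returns only the significant ones.

    ``bh_scope`` = "per-submodule" (default) corrects within each submodule's
    candidate list; "global" pools every (candidate, submodule) test before
    correction.
    """
    idx = net.neighbor_index()
    all_results: list[EnrichmentResult] = []
    for sub in submodules:
        all_results.extend(
            find_shared_interactors(net, sub, alpha, min_shared, neighbor_index=idx)
        )
    if bh_scope == "global":
        qvals = bh_adjust([r.p for r in all_results])
        all_results = [
            EnrichmentResult(
                r.candidate, r.submodule, r.universe, r.constituents_in_network,
                r.neighbor_count, r.overlap, r.p, q, r.role,
            )
            for r, q in zip(all_results, qvals)
        ]
    elif bh_scope != "per-submodule":
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    return [r for r in all_results if r.q < alpha]


def set_enrichment(
    query: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
    alpha: float = 1e-4,
) -> dict[str, tuple[float, bool]]:
    """Per-term hypergeometric upper-tail p with a Bonferroni-style cut.

    Returns term -> (p, significant at ``alpha``).  Terms with no universe
    overlap get p = 1.
    """
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    out = {}
    for term, members in annotation.items():
        K = len(members & universe)
        k = len(members & query)
        p = hypergeom_tail(k, len(universe), K, len(query)) if K else 1.0
        out[term] = (p, p < alpha)
    return out


def write_si_table(results: list[EnrichmentResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("si\tsubmodule\trole\tN\tK\tn\tk\tp\tq\n")
        for r in results:
            fh.write(
                f"{r.candidate}\t{r.submodule}\t{r.role}\t{r.universe}\t"
                f"{r.constituents_in_network}\t{r.neighbor_count}\t{r.overlap}\t"
                f"{r.p:.6g}\t{r.q:.6g}\n"
            )
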