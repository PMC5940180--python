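"""Ground-truth signaling scenario generator.

Emulates the statistical structure the pipeline assumes: a layered
source -> kinase -> target cascade with directed true edges; each kinase has
a sequence motif and its targets carry phospho-site windows embedding it;
NaCl-responsive fold-changes with multiplicative log-normal replicate noise;
source knockouts abolish all transitively downstream effects; and an
observed background network with false-negative edge deletions plus random
decoy PPI edges.  Every stage of the pipeline is testable against the
planted truth without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_model import (
    AMINO_ACIDS,
    CENTER_INDEX,
    DIRECTED,
    Edge,
    InteractionNetwork,
    PAD,
    PeptideMeasurement,
    PeptideTable,
    PPI,
    WINDOW_WIDTH,
)
from .motifs import MotifPattern, motif_matches

# small library of yeast-flavoured S/T kinase motifs: basophilic (PKA/Sch9
# style R-R-x-S, R-x-x-S), proline-directed (MAPK/CDK style S-P) and
# acidophilic (CK2 style S-x-x-E)
DEFAULT_MOTIF_LIBRARY: tuple[frozenset, ...] = (
    frozenset({(-3, "R"), (-2, "R")}),
    frozenset({(1, "P")}),
    frozenset({(1, "E"), (3, "E")}),
    frozenset({(-3, "R"), (-6, "R")}),
    frozenset({(1, "P"), (-2, "P")}),
    frozenset({(-3, "K"), (-2, "R")}),
)

WT_CONDITIONS = ("nacl_5min", "nacl_15min", "nacl_30min")
WT_REPLICATES = (3, 1, 1)
MUT_CONDITION = "mut_vs_wt"


@dataclass(frozen=True)
class RegulatedSite:
    protein: str
    site: int  # 1-based
    window: str
    kinase: str | None  # None for decoy sites
    direction: str | None  # "increased" / "decreased" for regulated sites


@dataclass
class TruthScenario:
    sources: tuple[str, ...]
    kinases: tuple[str, ...]
    targets: tuple[str, ...]
    decoy_proteins: tuple[str, ...]
    kinase_source: dict  # kinase -> source
    kinase_motif: dict  # kinase -> MotifPattern
    kinase_direction: dict  # kinase -> direction
    target_kinase: dict  # target -> kinase
    sites: list  # RegulatedSite, regulated then decoy
    true_edges: list  # Edge (directed)
    proteome: dict  # protein -> sequence
    effect: float

    @property
    def regulated_sites(self) -> list:
        return [s for s in self.sites if s.kinase is not None]

    @property
    def decoy_sites(self) -> list:
        return [s for s in self.sites if s.kinase is None]

    def mutant_labels(self) -> dict:
        """mutant label -> knocked-out source node."""
        return {s.lower(): s for s in self.sources}

    def downstream_sites(self, source: str) -> set:
        """(protein, site) pairs abolished by knocking out ``source``."""
        return {
            (s.protein, s.site)
            for s in self.regulated_sites
            if self.kinase_source[s.kinase] == source
        }


def _random_sequence(length: int, rng: np.random.Generator) -> list[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)]


def _window_at(seq: str, pos0: int) -> str:
    padded = PAD * CENTER_INDEX + seq + PAD * CENTER_INDEX
    return padded[pos0 : pos0 + WINDOW_WIDTH]


def generate_truth(
    n_sources: int = 2,
    n_kinases: int = 3,
    n_targets: int = 60,
    motif_library: tuple = DEFAULT_MOTIF_LIBRARY,
    rng: np.random.Generator | None = None,
    effect: float = 2.0,
    protein_length: int = 61,
    n_decoy_proteins: int = 400,
) -> TruthScenario:
    """Plant a layered cascade with motif-bearing target sites.

    Each kinase gets a distinct motif from the library and a fixed upstream
    source; targets are distributed round-robin over kinases and each
    carries one regulated site whose window embeds the kinase's motif.
    Decoy proteins contribute unregulated sites and background sequence; the
    decoy proteome is deliberately much larger than the foreground so that
    background residue frequencies are not distorted by the planted sites,
    as holds for a real proteome background.
    """
    if min(n_sources, n_kinases, n_targets) < 1:
        raise ValueError("counts must be >= 1")
    if len(motif_library) < n_kinases:
        raise ValueError(
            f"motif library of {len(motif_library)} smaller than {n_kinases} kinases"
        )
    if rng is None:
        rng = np.random.default_rng()

    sources = tuple(f"SRC{i + 1}" for i in range(n_sources))
    kinases = tuple(f"KIN{i + 1}" for i in range(n_kinases))
    targets = tuple(f"TGT{i + 1}" for i in range(n_targets))
    decoys = tuple(f"DEC{i + 1}" for i in range(n_decoy_proteins))

    kinase_source = {k: sources[i % n_sources] for i, k in enumerate(kinases)}
    kinase_motif = {
        k: MotifPattern(motif_library[i], "S/T", 0.0, 0)
        for i, k in enumerate(kinases)
    }
    kinase_direction = {
        k: ("increased" if i % 2 == 0 else "decreased")
        for i, k in enumerate(kinases)
    }
    target_kinase = {t: kinases[i % n_kinases] for i, t in enumerate(targets)}

    proteome: dict[str, str] = {}
    sites: list[RegulatedSite] = []
    for prot in (*sources, *kinases):
        proteome[prot] = "".join(_random_sequence(protein_length, rng))

    margin = CENTER_INDEX + 1
    for t in targets:
        seq = _random_sequence(protein_length, rng)
        kin = target_kinase[t]
        pos0 = int(rng.integers(margin, protein_length - margin))
        seq[pos0] = "S" if rng.random() < 0.7 else "T"
        for off, res in kinase_motif[kin].constraints:
            seq[pos0 + off] = res
        proteome[t] = "".join(seq)
        win = _window_at(proteome[t], pos0)
        assert motif_matches(win, kinase_motif[kin])
        sites.append(RegulatedSite(t, pos0 + 1, win, kin, kinase_direction[kin]))

    for d in decoys:
        seq = _random_sequence(protein_length, rng)
        pos0 = int(rng.integers(margin, protein_length - margin))
        seq[pos0] = "S" if rng.random() < 0.7 else "T"
        proteome[d] = "".join(seq)
        sites.append(RegulatedSite(d, pos0 + 1, _window_at(proteome[d], pos0), None, None))

    true_edges = [
        Edge(kinase_source[k], k, DIRECTED, "true-source-kinase") for k in kinases
    ] + [
        Edge(target_kinase[t], t, DIRECTED, "true-kinase-substrate") for t in targets
    ]
    return TruthScenario(
        sources=sources,
        kinases=kinases,
        targets=targets,
        decoy_proteins=decoys,
        kinase_source=kinase_source,
        kinase_motif=kinase_motif,
        kinase_direction=kinase_direction,
        target_kinase=target_kinase,
        sites=sites,
        true_edges=true_edges,
        proteome=proteome,
        effect=effect,
    )


def _noise(rng: np.random.Generator, dispersion: float, size: int) -> np.ndarray:
    return np.exp(rng.normal(0.0, dispersion, size=size))


def simulate_tables(
    truth: TruthScenario,
    dispersion: float = 0.15,
    rng: np.random.Generator | None = None,
    n_mut_replicates: int = 2,
) -> tuple[PeptideTable, dict]:
    """Simulate the wild-type table and one mutant table per source.

    Wild-type: each regulated site's linear fold-change is the planted
    effect (or its reciprocal for decreased sites) times per-replicate
    log-normal noise at every time point; decoy sites are pure noise around
    1.  Mutant tables carry mutant-vs-wild-type ratios: downstream sites
    lose the planted effect entirely (transitive knockout propagation), so
    their ratio centres on the reciprocal of the wild-type change; all other
    sites centre on 1.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if rng is None:
        rng = np.random.default_rng()

    wt_rows = []
    for s in truth.sites:
        base = 1.0
        if s.kinase is not None:
            base = truth.effect if s.direction == "increased" else 1.0 / truth.effect
        ratios = {
            cond: tuple(base * _noise(rng, dispersion, nrep))
            for cond, nrep in zip(WT_CONDITIONS, WT_REPLICATES)
        }
        wt_rows.append(
            PeptideMeasurement(
                peptide_id=f"pep_{s.protein}_{s.site}",
                protein_id=s.protein,
                site=s.site,
                window=s.window,
                ratios=ratios,
            )
        )
    wt = PeptideTable(rows=wt_rows, conditions=WT_CONDITIONS)

    mutants: dict[str, PeptideTable] = {}
    for label, source in truth.mutant_labels().items():
        down = truth.downstream_sites(source)
        rows = []
        for s in truth.sites:
            base = 1.0
            if (s.protein, s.site) in down:
                base = (
                    1.0 / truth.effect
                    if s.direction == "increased"
                    else truth.effect
                )
            rows.append(
                PeptideMeasurement(
                    peptide_id=f"pep_{s.protein}_{s.site}",
                    protein_id=s.protein,
                    site=s.site,
                    window=s.window,
                    ratios={
                        MUT_CONDITION: tuple(
                            base * _noise(rng, dispersion, n_mut_replicates)
                        )
                    },
                )
            )
        mutants[label] = PeptideTable(rows=rows, conditions=(MUT_CONDITION,))
    return wt, mutants


def simulate_background(
    truth: TruthScenario,
    fn_rate: float = 0.1,
    n_decoy_edges: int = 100,
    rng: np.random.Generator | None = None,
) -> InteractionNetwork:
    """Observed background: thinned true edges plus random decoy PPI edges.

    Each true (directed) edge is dropped independently with probability
    ``fn_rate``; decoy edges are undirected, between uniformly random node
    pairs, and never duplicate a true pair.
    """
    if not 0.0 <= fn_rate < 1.0:
        raise ValueError("fn_rate must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    all_nodes = (
        *truth.sources, *truth.kinases, *truth.targets, *truth.decoy_proteins,
    )
    net = InteractionNetwork(nodes=all_nodes)
    true_pairs = {frozenset((e.a, e.b)) for e in truth.true_edges}
    for e in truth.true_edges:
        if rng.random() >= fn_rate:
            net.add_edge(e)
    added = 0
    guard = 0
    existing: set[frozenset] = set()
    nodes = list(all_nodes)
    while added < n_decoy_edges and guard < 100 * max(n_decoy_edges, 1):
        guard += 1
        i, j = rng.integers(0, len(nodes), size=2)
        if i == j:
            continue
        pair = frozenset((nodes[i], nodes[j]))
        if pair in true_pairs or pair in existing:
            continue
        net.add_edge(Edge(nodes[i], nodes[j], PPI, "decoy"))
        existing.add(pair)
        added += 1
    return net


@dataclass
class RecoveryReport:
    kinases_as_si: float
    n_kinases: int
    intermediate_recovery: float  # conditional on recoverability
    intermediate_recovery_raw: float
    n_recoverable: int
    connection_recovery: float
    n_expected_connections: int
    false_inclusion: float
    consensus_nodes: int = 0
    consensus_edges: int = 0

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("metric\tvalue\n")
            for k, v in self.__dict__.items():
                fh.write(f"{k}\t{v}\n")


def score_recovery(
    consensus,
    truth: TruthScenario,
    si_results,
    observed_net: InteractionNetwork,
) -> RecoveryReport:
    """Score a consensus network against the planted truth.

    A planted kinase counts as *recoverable* only if the observed background
    still contains its source edge and at least two of its substrate edges
    (otherwise no neighbour-sharing method could implicate it); the headline
    intermediate-recovery fraction conditions on recoverability, and the raw
    fraction over all planted kinases is reported alongside.
    """
    si_nodes = {r.candidate for r in si_results}
    kin_as_si = (
        sum(1 for k in truth.kinases if k in si_nodes) / len(truth.kinases)
    )

    idx = observed_net.neighbor_index()
    directed_pairs = {
        (e.a, e.b) for e in observed_net.edges if e.etype == DIRECTED
    }
    recoverable = []
    for k in truth.kinases:
        src_ok = (truth.kinase_source[k], k) in directed_pairs or frozenset(
            (truth.kinase_source[k], k)
        ) in {frozenset((e.a, e.b)) for e in observed_net.edges}
        substrates = {t for t, kk in truth.target_kinase.items() if kk == k}
        if src_ok and len(idx.get(k, set()) & substrates) >= 2:
            recoverable.append(k)

    consensus_nodes = set(consensus.nodes)
    rec_cond = (
        sum(1 for k in recoverable if k in consensus_nodes) / len(recoverable)
        if recoverable
        else 1.0
    )
    rec_raw = sum(1 for k in truth.kinases if k in consensus_nodes) / len(
        truth.kinases
    )

    connected = {(p.source, p.target) for p, _ in consensus.paths}
    # expectation: every source regulating >= 1 recoverable kinase should
    # reach at least one of its dependent submodules
    expected = {truth.kinase_source[k] for k in recoverable}
    conn_rec = (
        sum(1 for s in expected if any(src == s for src, _ in connected))
        / len(expected)
        if expected
        else 1.0
    )

    planted = set(truth.sources) | set(truth.kinases) | set(truth.targets)
    protein_nodes = [
        n for n, (role, _) in consensus.nodes.items() if role != "submodule"
    ]
    false_inc = (
        sum(1 for n in protein_nodes if n not in planted) / len(protein_nodes)
        if protein_nodes
        else 0.0
    )
    return RecoveryReport(
        kinases_as_si=kin_as_si,
        n_kinases=len(truth.kinases),
        intermediate_recovery=rec_cond,
        intermediate_recovery_raw=rec_raw,
        n_recoverable=len(recoverable),
        connection_recovery=conn_rec,
        n_expected_connections=len(expected),
        false_inclusion=false_inc,
        consensus_nodes=len(consensus.nodes),
        consensus_edges=len(consensus.edges),
    )
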