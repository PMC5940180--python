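"""Core data types and readers/writers.

Everything downstream of mass-spectrometry quantification flows through three
containers: :class:`PeptideTable` (per-site fold-change measurements),
:class:`InteractionNetwork` (typed protein-interaction graph) and
:class:`RunConfig` (every threshold of the pipeline with the study defaults).

Conventions
-----------
* Phospho-site positions are 1-based residue indices in the protein.
* Sequence windows are 13 residues, positions labeled -6..+6 with the
  phospho-acceptor (S or T) at position 0.  Windows shorter than 13 at a
  protein terminus are padded with ``PAD`` (``_``), which carries no sequence
  information anywhere downstream.
* All fold-changes are linear ratios (strictly positive).
* TSV dialect: tab-separated, UTF-8, mandatory header, ``#`` comment lines.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger("phosphonet")

PAD = "_"
WINDOW_WIDTH = 13
CENTER_INDEX = WINDOW_WIDTH // 2
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PPI = "ppi-undirected"
DIRECTED = "directed"
EDGE_CLASSES = (PPI, DIRECTED)


class FormatError(ValueError):
    """Malformed input file (missing column, unknown edge class...)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


def normalize_window(window: str, width: int = WINDOW_WIDTH) -> str:
    """Upper-case and pad a site window to ``width`` centred on the acceptor.

    The phospho-acceptor may arrive lower-case (``s``/``t``); padding uses the
    neutral symbol ``_`` split evenly between termini (left-heavy remainder
    never occurs for odd widths and symmetric input).
    """
    w = window.strip().upper()
    if len(w) > width:
        raise ValidationError(f"window longer than {width}: {window!r}")
    if len(w) < width:
        if len(w) % 2 == 0:
            raise ValidationError(
                f"cannot centre even-length window {window!r}; pad explicitly"
            )
        side = (width - len(w)) // 2
        w = PAD * side + w + PAD * side
    center = w[width // 2]
    if center not in ("S", "T"):
        raise ValidationError(f"window centre must be S or T, got {center!r}")
    return w


@dataclass(frozen=True)
class PeptideMeasurement:
    """One phospho-site of one peptide with its quantification.

    ``ratios`` maps a condition label (e.g. ``"nacl_5min"``) to the list of
    linear fold-changes, one per replicate.
    """

    peptide_id: str
    protein_id: str
    site: int
    window: str
    ratios: Mapping[str, tuple[float, ...]]
    significant: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "window", normalize_window(self.window))
        if self.site < 1:
            raise ValidationError(f"{self.peptide_id}: site must be 1-based")
        clean: dict[str, tuple[float, ...]] = {}
        for cond, vals in self.ratios.items():
            vals = tuple(float(v) for v in vals)
            if not vals:
                raise ValidationError(f"{self.peptide_id}: no replicates for {cond}")
            if any(v <= 0 or not np.isfinite(v) for v in vals):
                raise ValidationError(
                    f"{self.peptide_id}: non-positive fold-change in {cond}"
                )
            clean[cond] = vals
        object.__setattr__(self, "ratios", clean)


@dataclass
class PeptideTable:
    """Validated collection of :class:`PeptideMeasurement` rows."""

    rows: list[PeptideMeasurement]
    conditions: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[PeptideMeasurement]:
        return iter(self.rows)

    def by_peptide(self) -> dict[str, list[PeptideMeasurement]]:
        out: dict[str, list[PeptideMeasurement]] = {}
        for r in self.rows:
            out.setdefault(r.peptide_id, []).append(r)
        return out


@dataclass(frozen=True)
class Edge:
    a: str
    b: str
    etype: str  # PPI (undirected) or DIRECTED (a -> b)
    provenance: str = ""

    def key(self) -> tuple:
        if self.etype == PPI:
            return (frozenset((self.a, self.b)), self.etype)
        return (self.a, self.b, self.etype)

    def pair(self) -> frozenset:
        return frozenset((self.a, self.b))


class InteractionNetwork:
    """Typed protein-interaction graph.

    Undirected PPI records are collapsed per unordered pair; a directed record
    between the same pair is kept as a distinct edge.  Self-loops are dropped
    with a warning.  Node roles (``protein`` / ``source`` / ``submodule`` /
    ``shared-interactor``) are assigned by later pipeline stages.
    """

    def __init__(self, edges: Iterable[Edge] = (), nodes: Iterable[str] = ()):
        self._edges: dict[tuple, Edge] = {}
        self.nodes: set[str] = set(nodes)
        self.roles: dict[str, str] = {}
        self.dropped_self_loops = 0
        for e in edges:
            self.add_edge(e)

    def add_edge(self, e: Edge) -> None:
        if e.a == e.b:
            self.dropped_self_loops += 1
            logger.warning("dropping self-loop on %s", e.a)
            return
        if e.etype not in EDGE_CLASSES:
            raise FormatError(f"unknown edge class {e.etype!r}")
        if e.etype == PPI and e.a > e.b:  # canonical orientation for storage
            e = Edge(e.b, e.a, e.etype, e.provenance)
        self._edges.setdefault(e.key(), e)
        self.nodes.update((e.a, e.b))

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges.values())

    def n_edges(self) -> int:
        return len(self._edges)

    def has_pair(self, a: str, b: str) -> bool:
        return any(e.pair() == frozenset((a, b)) for e in self._edges.values())

    def neighbors(self, node: str) -> set[str]:
        """All interaction partners, ignoring direction and multiplicity."""
        out = set()
        for e in self._edges.values():
            if e.a == node:
                out.add(e.b)
            elif e.b == node:
                out.add(e.a)
        return out

    def neighbor_index(self) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {n: set() for n in self.nodes}
        for e in self._edges.values():
            idx[e.a].add(e.b)
            idx[e.b].add(e.a)
        return idx

    def edges_between(self, a: str, b: str) -> list[Edge]:
        return [e for e in self._edges.values() if e.pair() == frozenset((a, b))]

    def copy(self) -> "InteractionNetwork":
        net = InteractionNetwork()
        net._edges = dict(self._edges)
        net.nodes = set(self.nodes)
        net.roles = dict(self.roles)
        return net

    def degree_multisets(self) -> dict[str, tuple]:
        """Sorted degree sequences per class (undirected; directed in/out)."""
        und: dict[str, int] = {n: 0 for n in self.nodes}
        din: dict[str, int] = {n: 0 for n in self.nodes}
        dout: dict[str, int] = {n: 0 for n in self.nodes}
        for e in self._edges.values():
            if e.etype == PPI:
                und[e.a] += 1
                und[e.b] += 1
            else:
                dout[e.a] += 1
                din[e.b] += 1
        return {
            "undirected": tuple(sorted(und.values())),
            "in": tuple(sorted(din.values())),
            "out": tuple(sorted(dout.values())),
        }

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        for n in self.nodes:
            g.add_node(n, role=self.roles.get(n, "protein"))
        for e in self._edges.values():
            if e.etype == PPI:
                g.add_edge(e.a, e.b, etype=e.etype, provenance=e.provenance)
                g.add_edge(e.b, e.a, etype=e.etype, provenance=e.provenance)
            else:
                g.add_edge(e.a, e.b, etype=e.etype, provenance=e.provenance)
        return g


@dataclass
class RunConfig:
    """All pipeline thresholds, defaulting to the study values."""

    # wild-type responsiveness
    wt_fold: float = 1.5            # 5-min rule, >=2 of 3 replicates
    wt_min_replicates: int = 2
    late_both_fold: float = 1.5     # both late time points
    late_single_fold: float = 2.0   # single late time point
    early_condition: str = "nacl_5min"
    late_conditions: tuple[str, ...] = ("nacl_15min", "nacl_30min")
    # mutant dependency: mutant -> (dual-replicate fold, single-replicate fold)
    mutant_thresholds: dict = field(
        default_factory=lambda: {
            "hog1": (1.3, 1.5),
            "pde2": (1.3, 1.5),
            "cdc14": (1.15, 1.3),
        }
    )
    # fallback for mutants not listed above (the hog1/pde2-strength rule)
    mutant_default_thresholds: tuple[float, float] = (1.3, 1.5)
    mutant_condition: str = "mut_vs_wt"
    # motif discovery (motif-x style)
    motif_min_occurrences: int = 10
    motif_significance: float = 1e-6
    motif_width: int = WINDOW_WIDTH
    # shared-interactor enrichment
    si_fdr: float = 0.05
    si_min_shared: int = 2
    si_bh_scope: str = "per-submodule"  # or "global"
    # kinase motif matching
    match_permutations: int = 1000
    match_fdr_cutoff: float = 0.002
    match_include_center: bool = False
    pwm_pseudocount: float = 1.0
    kinase_pseudocount: float = 0.01
    # ILP / ensemble
    max_path_length: int = 3
    ensemble_size: int = 1000
    holdout_probability: float = 0.05
    consensus_threshold: float = 0.75
    # evaluation
    scramble_swaps_per_edge: int = 10
    enrichment_alpha: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("holdout_probability", "consensus_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.ensemble_size < 1:
            raise ValidationError("ensemble_size must be >= 1")

    def rng(self, component: str) -> np.random.Generator:
        """Deterministic per-component substream of the master seed."""
        return np.random.default_rng(
            [self.seed, zlib.crc32(component.encode("utf-8"))]
        )

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# readers


def _read_tsv_rows(path: Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
            else:
                rows.append((lineno, fields))
    if header is None:
        raise FormatError(f"{path}: empty file")
    return header, rows


def read_peptide_table(path: str | Path, conditions: Sequence[str]) -> PeptideTable:
    """Read a peptide quantification TSV.

    Required columns: ``peptide``, ``protein``, ``position``, ``window`` and one
    column per condition label whose cell holds comma-separated replicate
    ratios.  Optional column ``significant`` (``1``/``0``/empty) carries the
    external count-based test verdict.  ``position``/``window`` cells may hold
    semicolon-separated lists for multiply-localized peptides; each site
    becomes its own row sharing the quantification.
    """
    path = Path(path)
    header, rows = _read_tsv_rows(path)
    required = ["peptide", "protein", "position", "window", *conditions]
    for col in required:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    idx = {c: header.index(c) for c in header}
    has_sig = "significant" in idx

    out: list[PeptideMeasurement] = []
    for lineno, fields in rows:
        if len(fields) < len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} columns")
        try:
            positions = [int(p) for p in fields[idx["position"]].split(";")]
            windows = fields[idx["window"]].split(";")
            if len(positions) != len(windows):
                raise ValidationError("position/window list length mismatch")
            ratios = {
                c: tuple(float(x) for x in fields[idx[c]].split(",") if x != "")
                for c in conditions
            }
            sig: bool | None = None
            if has_sig and fields[idx["significant"]] != "":
                sig = fields[idx["significant"]] in ("1", "true", "True")
            for pos, win in zip(positions, windows):
                out.append(
                    PeptideMeasurement(
                        peptide_id=fields[idx["peptide"]],
                        protein_id=fields[idx["protein"]],
                        site=pos,
                        window=win,
                        ratios=ratios,
                        significant=sig,
                    )
                )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return PeptideTable(rows=out, conditions=tuple(conditions))


def read_network(path: str | Path) -> InteractionNetwork:
    """Read an edge-list TSV with columns nodeA, nodeB, class, provenance."""
    path = Path(path)
    header, rows = _read_tsv_rows(path)
    for col in ("nodeA", "nodeB", "class"):
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    idx = {c: header.index(c) for c in header}
    net = InteractionNetwork()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#node\t"):
                net.nodes.add(line.rstrip("\n").split("\t")[1])
    for lineno, fields in rows:
        etype = fields[idx["class"]]
        if etype not in EDGE_CLASSES:
            raise FormatError(f"{path}:{lineno}: unknown edge class {etype!r}")
        prov = fields[idx["provenance"]] if "provenance" in idx else ""
        net.add_edge(Edge(fields[idx["nodeA"]], fields[idx["nodeB"]], etype, prov))
    if net.dropped_self_loops:
        logger.warning(
            "%s: dropped %d self-loop(s)", path, net.dropped_self_loops
        )
    return net


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Edge-list TSV; isolated nodes survive as ``#node`` comment lines."""
    connected = {n for e in net.edges for n in (e.a, e.b)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("nodeA\tnodeB\tclass\tprovenance\n")
        for n in sorted(net.nodes - connected):
            fh.write(f"#node\t{n}\n")
        for e in sorted(net.edges, key=lambda e: (e.a, e.b, e.etype)):
            fh.write(f"{e.a}\t{e.b}\t{e.etype}\t{e.provenance}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Background proteome reader (Biopython-backed)."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# consensus output


def write_consensus(consensus, outdir: str | Path) -> dict[str, Path]:
    """Write a consensus network as node TSV + edge TSV + GraphML.

    Returns the paths written.  The TSV edge list is the canonical
    interchange; the GraphML copy exists so external viewers can load it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    node_path = outdir / "consensus_nodes.tsv"
    edge_path = outdir / "consensus_edges.tsv"
    gml_path = outdir / "consensus.graphml"

    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("id\trole\tconfidence\n")
        for node in sorted(consensus.nodes):
            role, conf = consensus.nodes[node]
            fh.write(f"{node}\t{role}\t{conf:.6g}\n")
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\torientation\tkind\tconfidence\n")
        for (a, b, kind), conf in sorted(consensus.edges.items()):
            orient = "undirected" if kind == "ppi" else "directed"
            fh.write(f"{a}\t{b}\t{orient}\t{kind}\t{conf:.6g}\n")

    import networkx as nx

    g = nx.DiGraph()
    for node, (role, conf) in consensus.nodes.items():
        g.add_node(node, role=role, confidence=float(conf))
    for (a, b, kind), conf in consensus.edges.items():
        g.add_edge(a, b, kind=kind, confidence=float(conf))
    nx.write_graphml(g, gml_path)
    return {"nodes": node_path, "edges": edge_path, "graphml": gml_path}


def read_consensus_nodes(path: str | Path) -> dict[str, tuple[str, float]]:
    header, rows = _read_tsv_rows(Path(path))
    idx = {c: header.index(c) for c in header}
    return {
        f[idx["id"]]: (f[idx["role"]], float(f[idx["confidence"]]))
        for _, f in rows
    }
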