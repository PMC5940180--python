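"""Submodule construction.

A *module* is a (direction of change, phospho-motif) group of responsive
peptides; a *submodule* further splits a module by its mutant-dependency
signature.  Defective and amplified phenotypes for the same mutant form
separate submodules; a peptide affected by several mutants is duplicated
into each corresponding submodule; peptides with no phenotype in any mutant
form the module's single no-phenotype submodule.  Submodules are the target
units of the ILP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .motifs import MotifPattern, motif_matches
from .selection import DependencyCall, ResponsivenessCall, NONE

SOURCE_DEPENDENT = "source-dependent"
NO_PHENOTYPE = "no-phenotype"

# short phenotype annotations, mirroring "h-" / "p+" style strings
_MUTANT_ABBREV = {"hog1": "h", "pde2": "p", "cdc14": "c"}
_VERDICT_SIGN = {"defective": "-", "amplified": "+"}


def phenotype_label(mutant: str, verdict: str) -> str:
    return _MUTANT_ABBREV.get(mutant, mutant) + _VERDICT_SIGN[verdict]


@dataclass(frozen=True)
class Submodule:
    id: str
    direction: str
    motif_index: int
    motif: MotifPattern
    dependency: tuple[str, str] | None  # (mutant, verdict) or None
    constituents: frozenset  # of (peptide_id, protein_id, site)

    @property
    def phenotype_class(self) -> str:
        return NO_PHENOTYPE if self.dependency is None else SOURCE_DEPENDENT

    @property
    def proteins(self) -> frozenset:
        return frozenset(p for _, p, _ in self.constituents)

    @property
    def annotation(self) -> str:
        if self.dependency is None:
            return "none"
        return phenotype_label(*self.dependency)


def build_submodules(
    calls: list[ResponsivenessCall],
    deps: list[DependencyCall],
    motifs: list[tuple[MotifPattern, list[str]]],
    windows: dict[tuple[str, int], str],
) -> list[Submodule]:
    """Partition responsive, motif-matched peptides into submodules.

    ``windows`` maps (peptide id, site) to the 13-mer window used for motif
    assignment.  Assignment follows extraction order: a window belongs to the
    first emitted motif whose matched set produced it, which keeps motif
    membership disjoint.
    """
    window_to_motif: dict[str, int] = {}
    for i, (_, wins) in enumerate(motifs):
        for w in wins:
            window_to_motif.setdefault(w, i)

    dep_by_key: dict[tuple[str, int], list[DependencyCall]] = {}
    for d in deps:
        if d.verdict != NONE:
            dep_by_key.setdefault((d.peptide_id, d.site), []).append(d)

    # (direction, motif index) -> dependency signature -> constituents
    buckets: dict[tuple[str, int], dict[tuple[str, str] | None, set]] = {}
    for call in calls:
        if not call.responsive:
            continue
        key = (call.peptide_id, call.site)
        win = windows.get(key)
        if win is None or win not in window_to_motif:
            continue  # no-motif peptides are excluded from submodules
        mi = window_to_motif[win]
        module = buckets.setdefault((call.direction, mi), {})
        hits = dep_by_key.get(key, [])
        constituent = (call.peptide_id, call.protein_id, call.site)
        if hits:
            for d in hits:
                module.setdefault((d.mutant, d.verdict), set()).add(constituent)
        else:
            module.setdefault(None, set()).add(constituent)

    out: list[Submodule] = []
    for (direction, mi), sigs in sorted(
        buckets.items(), key=lambda kv: (kv[0][1], kv[0][0])
    ):
        pattern = motifs[mi][0]
        for sig in sorted(sigs, key=lambda s: ("",) if s is None else s):
            members = sigs[sig]
            tag = "none" if sig is None else phenotype_label(*sig)
            sid = f"M{mi}.{direction[:3]}.{tag}"
            out.append(
                Submodule(
                    id=sid,
                    direction=direction,
                    motif_index=mi,
                    motif=pattern,
                    dependency=sig,
                    constituents=frozenset(members),
                )
            )
    return out


def write_submodules(submodules: list[Submodule], path) -> None:
    """Constituent table: one row per (submodule, peptide, site)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("submodule\tdirection\tmotif\tphenotype\tpeptide\tprotein\tsite\n")
        for sub in submodules:
            for pep, prot, site in sorted(sub.constituents):
                fh.write(
                    f"{sub.id}\t{sub.direction}\t{sub.motif.display}\t"
                    f"{sub.annotation}\t{pep}\t{prot}\t{site}\n"
                )
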