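"""End-to-end orchestration: tables + network + proteome -> consensus.

This glues the stages together in the order of the method: wild-type
selection, per-mutant dependency calls, per-direction motif discovery,
submodule construction, shared-interactor enrichment, augmentation, path
enumeration, the ILP ensemble, consensus and no-phenotype add-back.
"""

from __future__ import annotations

from dataclasses import dataclass

from .enrichment import find_all_shared_interactors
from .inference import (
    AugmentedNetwork,
    ConsensusNetwork,
    Path,
    Solution,
    addback_no_phenotype,
    augment,
    build_consensus,
    enumerate_paths,
    run_ensemble,
)
from .io_model import InteractionNetwork, PeptideTable, RunConfig
from .motifs import build_background, discover_motifs
from .selection import (
    DECREASED,
    INCREASED,
    call_mutant_dependency,
    call_wt_responsive,
)
from .submodules import Submodule, build_submodules


@dataclass
class PipelineResult:
    calls: list
    deps: list
    motifs: list  # (MotifPattern, matched windows), both directions pooled
    submodules: list
    si_results: list
    aug: AugmentedNetwork
    catalog: list
    solutions: list
    consensus: ConsensusNetwork

    @property
    def n_responsive(self) -> int:
        return sum(1 for c in self.calls if c.responsive)


def run_pipeline(
    wt: PeptideTable,
    mutant_tables: dict[str, PeptideTable],
    network: InteractionNetwork,
    proteome: dict[str, str],
    cfg: RunConfig,
    sources: tuple[str, ...],
    source_of_mutant: dict[str, str],
) -> PipelineResult:
    calls = call_wt_responsive(wt, cfg)
    deps = []
    for mutant, table in mutant_tables.items():
        deps.extend(
            call_mutant_dependency(wt, table, mutant, cfg, wt_calls=calls)
        )

    windows = {(m.peptide_id, m.site): m.window for m in wt}
    background = build_background(proteome, "S") + build_background(proteome, "T")
    motifs = []
    for direction in (INCREASED, DECREASED):
        fg = [
            windows[(c.peptide_id, c.site)]
            for c in calls
            if c.responsive and c.direction == direction
        ]
        if fg:
            motifs.extend(discover_motifs(fg, background, cfg))

    submodules = build_submodules(calls, deps, motifs, windows)
    si_results = find_all_shared_interactors(
        network,
        submodules,
        alpha=cfg.si_fdr,
        min_shared=cfg.si_min_shared,
        bh_scope=cfg.si_bh_scope,
    )
    aug = augment(network, si_results, submodules, sources, source_of_mutant)
    catalog = enumerate_paths(aug, max_billed=cfg.max_path_length)
    solutions = run_ensemble(
        aug,
        catalog,
        n=cfg.ensemble_size,
        holdout=cfg.holdout_probability,
        rng=cfg.rng("ensemble"),
    )
    consensus = build_consensus(aug, solutions, cfg.consensus_threshold)
    consensus = addback_no_phenotype(consensus, si_results, submodules)
    return PipelineResult(
        calls=calls,
        deps=deps,
        motifs=motifs,
        submodules=submodules,
        si_results=si_results,
        aug=aug,
        catalog=catalog,
        solutions=solutions,
        consensus=consensus,
    )
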