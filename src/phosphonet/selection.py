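"""Wild-type responsiveness and mutant-dependency calling.

A peptide is NaCl-responsive if any of four rules fires: the external
count-based significance flag, a >=1.5-fold change in at least 2 of the 3
five-minute replicates, both late time points (15 and 30 min) changed
>=1.5-fold in the same direction, or a single late time point changed
>=2-fold.  Fold-changes are linear ratios; "changed" means ratio >= f or
ratio <= 1/f.

Mutant dependency compares the mutant's stress response to the wild type's
(ratio mutant/wild-type per replicate).  A change reproducibly *smaller* in
the mutant than wild type is "defective", reproducibly *greater* is
"amplified".  Thresholds are per-mutant (hog1/pde2: 1.3 with two replicates,
1.5 with one; the milder cdc14 allele: 1.15 / 1.3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .io_model import PeptideMeasurement, PeptideTable, RunConfig

logger = logging.getLogger("phosphonet")

INCREASED = "increased"
DECREASED = "decreased"

RULE_EXTERNAL = "external-significance"
RULE_EARLY = "5min-2-of-3"
RULE_LATE_BOTH = "late-both-1.5"
RULE_LATE_SINGLE = "late-single-2.0"

DEFECTIVE = "defective"
AMPLIFIED = "amplified"
NONE = "none"


@dataclass(frozen=True)
class ResponsivenessCall:
    peptide_id: str
    protein_id: str
    site: int
    responsive: bool
    direction: str | None = None  # INCREASED / DECREASED, iff responsive
    rules: tuple[str, ...] = ()
    ambiguous: bool = False


@dataclass(frozen=True)
class DependencyCall:
    peptide_id: str
    protein_id: str
    site: int
    mutant: str
    verdict: str  # DEFECTIVE / AMPLIFIED / NONE
    note: str = ""


def _changed(ratio: float, fold: float) -> int:
    """+1 if increased >= fold, -1 if decreased >= fold, 0 otherwise."""
    if ratio >= fold:
        return 1
    if ratio <= 1.0 / fold:
        return -1
    return 0


def _call_one(m: PeptideMeasurement, cfg: RunConfig) -> ResponsivenessCall:
    early = m.ratios.get(cfg.early_condition, ())
    late = [m.ratios[c][0] for c in cfg.late_conditions if c in m.ratios]

    fired: list[tuple[str, int]] = []  # (rule, direction sign)

    signs = [_changed(r, cfg.wt_fold) for r in early]
    n_up, n_down = signs.count(1), signs.count(-1)
    if max(n_up, n_down) >= cfg.wt_min_replicates:
        fired.append((RULE_EARLY, 1 if n_up >= n_down else -1))

    late_signs = [_changed(r, cfg.late_both_fold) for r in late]
    if len(late) >= 2 and late_signs.count(1) == len(late):
        fired.append((RULE_LATE_BOTH, 1))
    elif len(late) >= 2 and late_signs.count(-1) == len(late):
        fired.append((RULE_LATE_BOTH, -1))

    strong = [_changed(r, cfg.late_single_fold) for r in late]
    if any(s == 1 for s in strong) and not any(s == -1 for s in strong):
        fired.append((RULE_LATE_SINGLE, 1))
    elif any(s == -1 for s in strong) and not any(s == 1 for s in strong):
        fired.append((RULE_LATE_SINGLE, -1))

    if m.significant:
        fired.append((RULE_EXTERNAL, 0))

    if not fired:
        return ResponsivenessCall(m.peptide_id, m.protein_id, m.site, False)

    dirs = {s for _, s in fired if s != 0}
    if len(dirs) > 1:
        logger.warning(
            "%s: conflicting directions among firing rules; excluded",
            m.peptide_id,
        )
        return ResponsivenessCall(
            m.peptide_id, m.protein_id, m.site, False, ambiguous=True,
            rules=tuple(r for r, _ in fired),
        )
    if dirs:
        sign = dirs.pop()
    else:
        # only the external flag fired: majority sign of all log-ratios
        logsum = sum(math.log(r) for r in (*early, *late))
        if logsum == 0.0:
            return ResponsivenessCall(
                m.peptide_id, m.protein_id, m.site, False, ambiguous=True,
                rules=(RULE_EXTERNAL,),
            )
        sign = 1 if logsum > 0 else -1
    return ResponsivenessCall(
        m.peptide_id,
        m.protein_id,
        m.site,
        True,
        INCREASED if sign > 0 else DECREASED,
        tuple(r for r, _ in fired),
    )


def call_wt_responsive(table: PeptideTable, cfg: RunConfig) -> list[ResponsivenessCall]:
    """Apply the wild-type responsiveness rules to every measured site."""
    return [_call_one(m, cfg) for m in table]


def call_mutant_dependency(
    wt: PeptideTable,
    mut: PeptideTable,
    mutant: str,
    cfg: RunConfig,
    wt_calls: list[ResponsivenessCall] | None = None,
) -> list[DependencyCall]:
    """Call defective / amplified / none per responsive site for one mutant.

    ``mut`` holds mutant-vs-wild-type stress-response ratios per replicate
    under ``cfg.mutant_condition``.  The verdict is judged against the
    wild-type direction of change: for an increased site a mutant/wild-type
    ratio reproducibly below 1/threshold means the response is defective,
    reproducibly above threshold means amplified (mirrored for decreased
    sites).  Two or more replicates use the dual threshold and must all
    agree; a single detection uses the stricter single-replicate threshold.
    """
    if mutant in cfg.mutant_thresholds:
        dual, single = cfg.mutant_thresholds[mutant]
    else:
        dual, single = cfg.mutant_default_thresholds
        logger.info(
            "mutant %s not configured; using default thresholds %.2f/%.2f",
            mutant, dual, single,
        )
    if wt_calls is None:
        wt_calls = call_wt_responsive(wt, cfg)

    mut_by_key = {
        (m.peptide_id, m.site): m.ratios.get(cfg.mutant_condition, ()) for m in mut
    }
    out: list[DependencyCall] = []
    for call in wt_calls:
        if not call.responsive:
            continue
        key = (call.peptide_id, call.site)
        ratios = mut_by_key.get(key, ())
        if not ratios:
            out.append(
                DependencyCall(
                    call.peptide_id, call.protein_id, call.site, mutant, NONE,
                    note="not-detected",
                )
            )
            continue
        fold = dual if len(ratios) >= 2 else single
        signs = {_changed(r, fold) for r in ratios}
        wt_sign = 1 if call.direction == INCREASED else -1
        if signs == {-wt_sign}:
            verdict = DEFECTIVE
        elif signs == {wt_sign}:
            verdict = AMPLIFIED
        else:
            verdict = NONE  # below threshold or irreproducible direction
        out.append(
            DependencyCall(call.peptide_id, call.protein_id, call.site, mutant, verdict)
        )
    return out
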