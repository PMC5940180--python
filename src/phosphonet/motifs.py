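"""Iterative phosphorylation-motif extraction (motif-x style).

Given a foreground of 13-residue windows centred on S/T and a background of
proteome windows, motifs are grown greedily: at each step the
(position, residue) pair with the smallest binomial upper-tail probability —
foreground count k out of n informative windows against the background
residue frequency at that position — is fixed, both window sets are
restricted to matching windows, and the loop repeats until no pair reaches
both the significance threshold and the minimum occurrence count.  The
emitted motif's matched windows are removed from the foreground and
extraction restarts, so motif membership is disjoint by construction.

S-centred and T-centred windows run separately; motifs with identical
constraint sets from both runs are merged into a single S/T motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_model import AMINO_ACIDS, CENTER_INDEX, PAD, RunConfig, WINDOW_WIDTH

logger = logging.getLogger("phosphonet")

POSITIONS = tuple(p for p in range(-CENTER_INDEX, CENTER_INDEX + 1) if p != 0)


@dataclass(frozen=True)
class MotifPattern:
    """A motif: fixed (offset, residue) constraints around an S/T centre."""

    constraints: frozenset  # of (position in -6..+6 excl. 0, residue)
    center: str  # "S", "T" or "S/T"
    significance: float  # binomial p of the last accepted constraint
    matched_count: int

    @property
    def display(self) -> str:
        lo = min([p for p, _ in self.constraints] + [0])
        hi = max([p for p, _ in self.constraints] + [0])
        fixed = dict(self.constraints)
        parts = []
        for p in range(lo, hi + 1):
            if p == 0:
                parts.append(self.center)
            else:
                parts.append(fixed.get(p, "x"))
        return "-".join(parts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.display


def motif_matches(window: str, pattern: MotifPattern) -> bool:
    """True iff the window satisfies the centre and every fixed constraint."""
    if len(window) != WINDOW_WIDTH:
        raise ValueError(f"window must be {WINDOW_WIDTH} long: {window!r}")
    if window[CENTER_INDEX] not in pattern.center.split("/"):
        return False
    return all(window[CENTER_INDEX + p] == r for p, r in pattern.constraints)


def build_background(proteome: dict[str, str], center: str) -> list[str]:
    """One padded 13-mer per occurrence of ``center`` in the proteome."""
    if not proteome:
        raise ValueError("empty proteome")
    windows = []
    w = CENTER_INDEX
    for seq in proteome.values():
        padded = PAD * w + seq + PAD * w
        for i, aa in enumerate(seq):
            if aa == center:
                windows.append(padded[i : i + WINDOW_WIDTH])
    return windows


def _counts(windows: list[str]) -> np.ndarray:
    """(width, 21) counts; last column counts the padding symbol."""
    alphabet = AMINO_ACIDS + PAD
    lut = np.full(128, -1, dtype=np.int64)
    for i, aa in enumerate(alphabet):
        lut[ord(aa)] = i
    arr = np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8)
    arr = lut[arr].reshape(len(windows), WINDOW_WIDTH)
    out = np.zeros((WINDOW_WIDTH, len(alphabet)), dtype=np.int64)
    for j in range(WINDOW_WIDTH):
        out[j] = np.bincount(arr[:, j], minlength=len(alphabet))
    return out


def _best_constraint(fg, bg, fixed, cfg):
    """Most significant unfixed (position, residue) pair, or None.

    Tie-break for equal p: larger foreground count, then position ascending,
    then residue alphabetical — fixed so extraction is deterministic.
    """
    fg_counts = _counts(fg)
    bg_counts = _counts(bg)
    fg_inform = fg_counts[:, :20].sum(axis=1)  # pads carry no information
    bg_inform = bg_counts[:, :20].sum(axis=1)

    best = None  # (p, -k, pos, residue)
    for pos in POSITIONS:
        if pos in {p for p, _ in fixed}:
            continue
        j = CENTER_INDEX + pos
        n = int(fg_inform[j])
        if n == 0 or bg_inform[j] == 0:
            continue
        for ai, res in enumerate(AMINO_ACIDS):
            k = int(fg_counts[j, ai])
            if k < cfg.motif_min_occurrences:
                continue
            freq = bg_counts[j, ai] / bg_inform[j]
            if freq == 0.0:
                freq = 1.0 / (bg_inform[j] + 1)  # avoid degenerate p = 0
            p = float(stats.binom.sf(k - 1, n, freq))
            cand = (p, -k, pos, res)
            if best is None or cand < best:
                best = cand
    if best is not None and best[0] < cfg.motif_significance:
        return best
    return None


def _filter(windows: list[str], pos: int, res: str) -> list[str]:
    j = CENTER_INDEX + pos
    return [w for w in windows if w[j] == res]


def _discover_center(fg, bg, center, cfg):
    results = []
    remaining = list(fg)
    while len(remaining) >= cfg.motif_min_occurrences:
        cur_fg, cur_bg = list(remaining), list(bg)
        fixed: set[tuple[int, str]] = set()
        last_p = 1.0
        while True:
            hit = _best_constraint(cur_fg, cur_bg, fixed, cfg)
            if hit is None:
                break
            p, _, pos, res = hit
            fixed.add((pos, res))
            last_p = p
            cur_fg = _filter(cur_fg, pos, res)
            cur_bg = _filter(cur_bg, pos, res)
        if not fixed:
            break
        pattern = MotifPattern(frozenset(fixed), center, last_p, len(cur_fg))
        results.append((pattern, cur_fg))
        matched = set(cur_fg)
        # remove by content: identical windows in different peptides share fate
        remaining = [w for w in remaining if w not in matched]
    return results


def discover_motifs(
    foreground: list[str], background: list[str], cfg: RunConfig
) -> list[tuple[MotifPattern, list[str]]]:
    """Run greedy extraction per centre residue and merge identical S/T motifs.

    Returns (pattern, matched foreground windows) in extraction order.
    """
    if len(foreground) < cfg.motif_min_occurrences:
        logger.warning(
            "foreground of %d below occurrence minimum %d; no motifs",
            len(foreground), cfg.motif_min_occurrences,
        )
        return []
    results: list[tuple[MotifPattern, list[str]]] = []
    per_center = {}
    for center in ("S", "T"):
        fg = [w for w in foreground if w[CENTER_INDEX] == center]
        bg = [w for w in background if w[CENTER_INDEX] == center]
        per_center[center] = _discover_center(fg, bg, center, cfg) if fg and bg else []

    t_by_constraints = {pat.constraints: (pat, wins) for pat, wins in per_center["T"]}
    merged_t = set()
    for pat, wins in per_center["S"]:
        if pat.constraints in t_by_constraints:
            t_pat, t_wins = t_by_constraints[pat.constraints]
            merged = MotifPattern(
                pat.constraints,
                "S/T",
                min(pat.significance, t_pat.significance),
                pat.matched_count + t_pat.matched_count,
            )
            results.append((merged, wins + t_wins))
            merged_t.add(pat.constraints)
        else:
            results.append((pat, wins))
    for pat, wins in per_center["T"]:
        if pat.constraints not in merged_t:
            results.append((pat, wins))
    return results


def assign_windows(
    motifs: list[tuple[MotifPattern, list[str]]]
) -> dict[str, int]:
    """Map window content -> index of the motif that claimed it."""
    assignment: dict[str, int] = {}
    for i, (_, wins) in enumerate(motifs):
        for w in wins:
            assignment.setdefault(w, i)
    return assignment
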