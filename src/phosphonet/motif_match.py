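"""Kinase specificity matching by Kullback-Leibler divergence.

Each motif module's peptide windows are summarized as a position weight
matrix (PWM, +1 pseudocount per residue); kinase specificities arrive as
protein-array signal-intensity matrices and are converted to PWMs with a
small pseudocount so every entry is strictly positive.  A module-kinase
match is scored as D(module || kinase) in bits, summed over the positions
shared by both matrices (the phospho-acceptor column is excluded by
default: the arrays fix it, so it carries no information).

Significance is empirical: each kinase PWM is randomized by permuting the
residue probabilities within every position column and then shuffling the
column order; the pooled scores over all kinases and permutations form the
module's null, and FDR = fraction of null scores strictly smaller than the
observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import AMINO_ACIDS, CENTER_INDEX, PAD, ValidationError
from .motifs import MotifPattern

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class PWM:
    """Per-position amino-acid probabilities.

    ``matrix`` has one row per entry of ``positions`` (offsets relative to
    the phospho-acceptor) and 20 residue columns; every row sums to 1 and is
    strictly positive.
    """

    positions: tuple[int, ...]
    matrix: np.ndarray  # (len(positions), 20)
    provenance: str  # "module" or "kinase"
    pseudocount: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.positions), 20):
            raise ValidationError("PWM shape does not match positions")
        if not np.all(m > 0):
            raise ValidationError("PWM entries must be strictly positive")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("PWM rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    def row(self, position: int) -> np.ndarray:
        return self.matrix[self.positions.index(position)]


def build_module_pwm(windows: list[str], pseudocount: float = 1.0) -> PWM:
    """PWM of a module's windows: (count + pseudocount) / (n + 20*pseudocount).

    Padding symbols are excluded from both the counts and the normalization,
    so terminal windows contribute only their informative positions.
    """
    if not windows:
        raise ValueError("cannot build a PWM from zero windows")
    positions = tuple(range(-CENTER_INDEX, CENTER_INDEX + 1))
    counts = np.zeros((len(positions), 20))
    for w in windows:
        for j, aa in enumerate(w):
            if aa != PAD:
                counts[j, _AA_INDEX[aa]] += 1
    counts += pseudocount
    matrix = counts / counts.sum(axis=1, keepdims=True)
    return PWM(positions, matrix, "module", pseudocount)


def build_kinase_pwm(intensities: pd.DataFrame, pseudocount: float = 0.01) -> PWM:
    """Convert a position x residue signal-intensity table to a PWM.

    Rows are indexed by integer position offsets, columns by residue.
    Each position's frequencies are (intensity + pseudocount) normalized by
    the position's summed (intensity + pseudocount), so residues undetected
    on the array keep strictly positive probability.
    """
    if (intensities.values < 0).any():
        raise ValidationError("negative intensity in kinase matrix")
    cols = list(intensities.columns)
    if sorted(cols) != sorted(AMINO_ACIDS):
        raise ValidationError("kinase matrix must have exactly the 20 residues")
    ordered = intensities[list(AMINO_ACIDS)]
    positions = tuple(int(p) for p in ordered.index)
    m = ordered.to_numpy(dtype=float) + pseudocount
    m /= m.sum(axis=1, keepdims=True)
    return PWM(positions, m, "kinase", pseudocount)


def kld(
    pwm_a: PWM, pwm_b: PWM, include_center: bool = False
) -> float:
    """D(a || b) in bits over the positions shared by both PWMs."""
    shared = [
        p
        for p in pwm_a.positions
        if p in pwm_b.positions and (include_center or p != 0)
    ]
    if not shared:
        raise ValueError("PWMs share no positions")
    total = 0.0
    for p in shared:
        a, b = pwm_a.row(p), pwm_b.row(p)
        total += float(np.sum(a * np.log2(a / b)))
    return total


@dataclass(frozen=True)
class MotifMatchResult:
    module_id: str
    kinase_id: str
    kld: float
    fdr: float
    designated: bool
    group: str  # kinase specificity group, or "unknown-recognition"


def motif_class(pattern: MotifPattern) -> str:
    """Coarse specificity class of a module motif.

    Proline-directed if +1 is fixed to P; basophilic if any upstream position
    is fixed to R/K; acidophilic if any fixed residue is D/E; else "other".
    """
    fixed = dict(pattern.constraints)
    if fixed.get(1) == "P":
        return "proline-directed"
    if any(r in "RK" for p, r in pattern.constraints if p < 0):
        return "basophilic"
    if any(r in "DE" for _, r in pattern.constraints):
        return "acidophilic"
    return "other"


def _null_scores(
    module: PWM, kinase: PWM, n_perm: int, rng: np.random.Generator,
    include_center: bool,
) -> np.ndarray:
    """KLD of the module against ``n_perm`` randomizations of one kinase PWM.

    Randomization permutes values within each position column, then shuffles
    the column (position) order; both preserve each column's multiset of
    probabilities, so the result is still a valid PWM.
    """
    shared = [
        p
        for p in module.positions
        if p in kinase.positions and (include_center or p != 0)
    ]
    a = np.stack([module.row(p) for p in shared])  # (P, 20)
    q_full = kinase.matrix  # (Pk, 20); permute over the kinase's full range
    stack = np.broadcast_to(q_full, (n_perm, *q_full.shape)).copy()
    stack = rng.permuted(stack, axis=2)  # within-column (per-position) values
    order = np.argsort(rng.random((n_perm, q_full.shape[0])), axis=1)
    stack = np.take_along_axis(stack, order[:, :, None], axis=1)  # column shuffle
    rows = [kinase.positions.index(p) for p in shared]
    q = stack[:, rows, :]  # (n_perm, P, 20)
    const = float(np.sum(a * np.log2(a)))
    return const - np.einsum("pr,npr->n", a, np.log2(q))


def permutation_null(
    module: PWM,
    kinases: dict[str, PWM],
    n_perm: int,
    rng: np.random.Generator,
    include_center: bool = False,
) -> np.ndarray:
    """Pooled null KLD scores: ``len(kinases) * n_perm`` values."""
    return np.concatenate(
        [
            _null_scores(module, pwm, n_perm, rng, include_center)
            for _, pwm in sorted(kinases.items())
        ]
    )


def match_fdr(
    module_id: str,
    module: PWM,
    kinases: dict[str, PWM],
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    fdr_cutoff: float = 0.002,
    groups: dict[str, str] | None = None,
    module_pattern: MotifPattern | None = None,
    include_center: bool = False,
) -> list[MotifMatchResult]:
    """Score a module PWM against every kinase PWM with a permutation FDR.

    The null pool has ``len(kinases) * n_perm`` scores; FDR is the fraction
    of null scores strictly smaller than the observed KLD.  A kinase is a
    designated match if its FDR is below the cutoff and its declared
    specificity group (from ``groups``) is compatible with the module's
    motif class; kinases absent from ``groups`` are labeled
    "unknown-recognition" and never designated.
    """
    if rng is None:
        rng = np.random.default_rng()
    observed = {
        kid: kld(module, pwm, include_center) for kid, pwm in kinases.items()
    }
    null = permutation_null(module, kinases, n_perm, rng, include_center)
    mclass = motif_class(module_pattern) if module_pattern is not None else None
    out = []
    for kid in sorted(kinases):
        obs = observed[kid]
        fdr = float(np.count_nonzero(null < obs)) / len(null)
        group = (groups or {}).get(kid, "unknown-recognition")
        compatible = (
            group != "unknown-recognition"
            and (mclass is None or group == mclass)
        )
        out.append(
            MotifMatchResult(module_id, kid, obs, fdr, fdr < fdr_cutoff and compatible, group)
        )
    return sorted(out, key=lambda r: (r.fdr, r.kld, r.kinase_id))


def write_pwm_table(pwms: dict[str, PWM], path) -> None:
    """Serialize PWMs as a long TSV (module, position, residue, probability)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tposition\tresidue\tprobability\n")
        for mid, pwm in pwms.items():
            for i, pos in enumerate(pwm.positions):
                for j, aa in enumerate(AMINO_ACIDS):
                    fh.write(f"{mid}\t{pos}\t{aa}\t{pwm.matrix[i, j]:.6g}\n")


def read_kinase_intensities(path) -> dict[str, pd.DataFrame]:
    """Read a kinase intensity TSV: columns kinase, position, then residues."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for kid, grp in df.groupby("kinase"):
        out[kid] = grp.set_index("position")[list(AMINO_ACIDS)]
    return out
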