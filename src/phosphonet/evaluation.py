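"""Evaluation: precision-recall against true-positive regulators,
degree-preserving network scrambling, and co-IP interactor calling.

Precision is the fraction of retained network proteins that are true
positives, recall the fraction of the true-positive list retrieved;
submodule and source nodes are excluded from both.  Nodes enter the curve
in descending confidence, and a confidence tie group enters as one atomic
point (ensemble ties are real, so ordering within a group would be
arbitrary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import DIRECTED, Edge, InteractionNetwork, PPI

logger = logging.getLogger("phosphonet")


@dataclass
class PRCurve:
    thresholds: np.ndarray  # descending confidence levels
    precision: np.ndarray
    recall: np.ndarray
    n_retained: np.ndarray

    @property
    def auc(self) -> float:
        if len(self.recall) == 0:
            return 0.0
        r = np.concatenate([[0.0], self.recall])
        p = np.concatenate(
            [[self.precision[0] if len(self.precision) else 0.0], self.precision]
        )
        return float(np.trapezoid(p, r))


def precision_recall(consensus, tp: set[str]) -> PRCurve:
    """Sweep node confidence with atomic tie groups.

    ``consensus`` is a ConsensusNetwork; nodes with role "submodule" or
    "source" are excluded from both numerator and denominator.
    """
    if not tp:
        raise ValueError("true-positive list is empty")
    scored = [
        (conf, node)
        for node, (role, conf) in consensus.nodes.items()
        if role not in ("submodule", "source")
    ]
    if not scored:
        return PRCurve(np.array([]), np.array([]), np.array([]), np.array([]))
    if not any(node in tp for _, node in scored):
        logger.warning("no true positive appears in the network")
    levels = sorted({c for c, _ in scored}, reverse=True)
    thr, prec, rec, nret = [], [], [], []
    for level in levels:
        retained = [node for conf, node in scored if conf >= level]
        hits = sum(1 for node in retained if node in tp)
        thr.append(level)
        prec.append(hits / len(retained))
        rec.append(hits / len(tp))
        nret.append(len(retained))
    return PRCurve(np.array(thr), np.array(prec), np.array(rec), np.array(nret))


def rank_precision_recall(ranking: list[str], tp: set[str]) -> PRCurve:
    """PR curve for an externally ranked node list (competitor outputs)."""
    if not tp:
        raise ValueError("true-positive list is empty")
    prec, rec = [], []
    hits = 0
    for i, node in enumerate(ranking, start=1):
        hits += node in tp
        prec.append(hits / i)
        rec.append(hits / len(tp))
    n = np.arange(1, len(ranking) + 1)
    return PRCurve(-n.astype(float), np.array(prec), np.array(rec), n)


def scramble_network(
    net: InteractionNetwork,
    n_swaps_per_edge: int = 10,
    rng: np.random.Generator | None = None,
    max_tries_factor: int = 100,
) -> InteractionNetwork:
    """Degree-preserving randomization by double-edge swaps, per edge class.

    Undirected swaps preserve every node's undirected degree; directed swaps
    ((a->b),(c->d) -> (a->d),(c->b)) preserve in- and out-degrees.  Swaps
    that would create a self-loop or a duplicate (pair, class) record are
    rejected and retried.
    """
    if rng is None:
        rng = np.random.default_rng()
    und = [e for e in net.edges if e.etype == PPI]
    dirs = [e for e in net.edges if e.etype == DIRECTED]

    def swap_class(edges: list[Edge], etype: str) -> list[Edge]:
        if len(edges) < 2:
            logger.info("too few %s edges to scramble", etype)
            return edges
        edges = list(edges)
        existing = {frozenset((e.a, e.b)) if etype == PPI else (e.a, e.b)
                    for e in edges}
        target = n_swaps_per_edge * len(edges)
        done = tries = 0
        while done < target and tries < max_tries_factor * target:
            tries += 1
            i, j = rng.integers(0, len(edges), size=2)
            if i == j:
                continue
            e1, e2 = edges[i], edges[j]
            if etype == PPI:
                a, b = e1.a, e1.b
                c, d = e2.a, e2.b
                if rng.random() < 0.5:
                    b, a = a, b  # undirected: orientation is arbitrary
                new1, new2 = (a, d), (c, b)
                keys = (frozenset(new1), frozenset(new2))
            else:
                new1, new2 = (e1.a, e2.b), (e2.a, e1.b)
                keys = (new1, new2)
            if new1[0] == new1[1] or new2[0] == new2[1]:
                continue
            if keys[0] in existing or keys[1] in existing or keys[0] == keys[1]:
                continue
            old_keys = (
                (frozenset((e1.a, e1.b)), frozenset((e2.a, e2.b)))
                if etype == PPI
                else ((e1.a, e1.b), (e2.a, e2.b))
            )
            existing.difference_update(old_keys)
            existing.update(keys)
            edges[i] = Edge(new1[0], new1[1], etype, e1.provenance)
            edges[j] = Edge(new2[0], new2[1], etype, e2.provenance)
            done += 1
        if done < target:
            logger.warning(
                "%s scrambling reached only %d/%d swaps", etype, done, target
            )
        return edges

    out = InteractionNetwork(nodes=net.nodes)
    for e in swap_class(und, PPI):
        out.add_edge(e)
    for e in swap_class(dirs, DIRECTED):
        out.add_edge(e)
    out.roles = dict(net.roles)
    return out


# ---------------------------------------------------------------------------
# co-IP interactor calling


def coip_call_interactors(
    tagged: pd.DataFrame,
    untagged: pd.DataFrame,
    enrichment_fold: float = 2.0,
    salt_fold: float = 1.5,
    impute_quantile: float = 0.01,
) -> pd.DataFrame:
    """Call bait interactors from GFP pulldown intensities.

    Both tables are long format with columns ``protein``, ``replicate``,
    ``timepoint`` ("pre" or "10min") and ``intensity``.  A protein is an
    interactor if it was detected in both biological replicates at either
    timepoint and is at least ``enrichment_fold`` more abundant than the
    untagged control in both replicates at that timepoint.  Missing values
    are imputed with the run's 1st-percentile intensity (a run is one
    replicate x timepoint acquisition); proteins entirely absent from the
    untagged table take the untagged run's imputed floor, which is the most
    permissive call and is flagged.

    Salt dependence: |log2(10min/pre)| >= log2(``salt_fold``) with the same
    sign in both replicates (after imputation).

    Returns a DataFrame indexed by protein with columns ``interactor``,
    ``salt_dependent``, ``control_imputed``.
    """
    required = {"protein", "replicate", "timepoint", "intensity"}
    for name, df in (("tagged", tagged), ("untagged", untagged)):
        if not required <= set(df.columns):
            raise ValueError(f"{name} table must have columns {sorted(required)}")

    def pivot(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
        wide = df.pivot_table(
            index="protein", columns=["replicate", "timepoint"],
            values="intensity", aggfunc="first",
        )
        floors = {
            col: np.nanquantile(df.loc[
                (df["replicate"] == col[0]) & (df["timepoint"] == col[1]),
                "intensity",
            ].to_numpy(dtype=float), impute_quantile)
            for col in wide.columns
        }
        return wide, floors

    twide, tfloors = pivot(tagged)
    uwide, ufloors = pivot(untagged)
    # the replicate/timepoint design spans both tables: a replicate missing
    # from the tagged table still counts as a non-detection
    all_cols = set(twide.columns) | set(uwide.columns)
    reps = sorted({c[0] for c in all_cols})
    tps = [tp for tp in ("pre", "10min") if any(c[1] == tp for c in all_cols)]

    records = []
    for prot, row in twide.iterrows():
        detected = {
            (r, tp): not np.isnan(row.get((r, tp), np.nan)) for r in reps for tp in tps
        }
        vals = {
            (r, tp): (
                row.get((r, tp), np.nan)
                if detected[(r, tp)]
                else tfloors.get((r, tp), np.nan)
            )
            for r in reps
            for tp in tps
        }
        control_imputed = prot not in uwide.index
        uvals = {}
        for r in reps:
            for tp in tps:
                u = uwide.loc[prot].get((r, tp), np.nan) if not control_imputed else np.nan
                if np.isnan(u):
                    u = ufloors.get((r, tp), np.nan)
                uvals[(r, tp)] = u

        interactor = False
        for tp in tps:
            if all(detected.get((r, tp), False) for r in reps) and all(
                vals[(r, tp)] >= enrichment_fold * uvals[(r, tp)] for r in reps
            ):
                interactor = True
                break

        salt = False
        if {"pre", "10min"} <= set(tps):
            logs = [
                np.log2(vals[(r, "10min")] / vals[(r, "pre")]) for r in reps
            ]
            cut = np.log2(salt_fold)
            salt = all(l >= cut for l in logs) or all(l <= -cut for l in logs)
        records.append(
            {
                "protein": prot,
                "interactor": interactor,
                "salt_dependent": bool(interactor and salt),
                "control_imputed": control_imputed,
            }
        )
    return pd.DataFrame.from_records(records).set_index("protein")
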