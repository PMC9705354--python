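"""Structural consistency: a prior-free index of link predictability.

A network is structurally consistent when removing a small random edge set
E_p barely changes its eigen-structure, so the first-order perturbed matrix
A~ built from the retained edges still ranks the removed edges highly.  The
index is

    delta = |E^l  intersect  E_p| / l,

where l = |E_p| and E^l are the top-l node pairs outside the retained set
E_r, ranked by their A~ value in descending order.  delta in [0, 1]; higher
means the network's existing structure predicts its own missing links
better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .network import BilayerNetwork, sample_perturbation_split
from .spm import perturb_matrix

ABLATION_MODES = ("none", "lm", "lm+sl", "lm+sm")


@dataclass
class ConsistencyReport:
    """Per-repeat structural consistency values with mean and sample std."""

    deltas: list[float]
    fraction: float
    repeats: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.deltas))

    @property
    def std(self) -> float:
        if len(self.deltas) < 2:
            return 0.0
        return float(np.std(self.deltas, ddof=1))


def recovery_fraction(predicted_top, removed) -> float:
    """Fraction of removed edges recovered in the predicted top-l list.

    Edges are unordered node pairs; orientation is normalised before the
    set intersection.  This is the scoring core of the structural
    consistency index.
    """
    removed_set = {tuple(sorted(e)) for e in removed}
    top_set = {tuple(sorted(e)) for e in predicted_top}
    if not removed_set:
        raise ValueError("perturbation set is empty (l = 0)")
    return len(top_set & removed_set) / len(removed_set)


def rank_non_retained_pairs(
    net: BilayerNetwork, a_tilde: np.ndarray, e_r: np.ndarray
) -> np.ndarray:
    """All node pairs (i < j) outside E_r, sorted by A~ score descending.

    The candidate pool is the perturbation set plus every unobserved pair;
    ties break lexicographically on the node pair for determinism.
    """
    big = net.size
    iu, ju = np.triu_indices(big, k=1)
    retained = np.zeros((big, big), dtype=bool)
    if len(e_r):
        retained[e_r[:, 0], e_r[:, 1]] = True
        retained[e_r[:, 1], e_r[:, 0]] = True
    keep = ~retained[iu, ju]
    ci, cj = iu[keep], ju[keep]
    scores = a_tilde[ci, cj]
    order = np.lexsort((cj, ci, -scores))
    return np.column_stack([ci[order], cj[order]])


def consistency_from_split(split) -> float:
    """Structural consistency of one concrete perturbation split."""
    n_removed = len(split.e_p)
    if n_removed == 0:
        raise ValueError(
            "perturbation set is empty; increase fraction or edge count"
        )
    a_tilde = perturb_matrix(split.a_r, split.a_p)
    ranked = rank_non_retained_pairs(split.net, a_tilde, split.e_r)
    return recovery_fraction(ranked[:n_removed], split.e_p)


def structural_consistency_once(
    net: BilayerNetwork, fraction: float = 0.1, seed: int = 0
) -> float:
    """One structural-consistency evaluation with a fresh random E_p."""
    return consistency_from_split(
        sample_perturbation_split(
            net, fraction=fraction, seed=seed, edge_pool="all_edges"
        )
    )


def structural_consistency(
    net: BilayerNetwork,
    fraction: float = 0.1,
    repeats: int = 20,
    seed: int = 0,
) -> ConsistencyReport:
    """Mean +/- std of structural consistency over repeated random E_p."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    deltas = [
        structural_consistency_once(net, fraction, derive_seed(seed, r))
        for r in range(repeats)
    ]
    return ConsistencyReport(
        deltas=deltas, fraction=float(fraction),
        repeats=int(repeats), seed=int(seed),
    )


def ablate(net: BilayerNetwork, mode: str) -> BilayerNetwork:
    """Zero out similarity blocks to form the reduced comparison networks.

    ``lm`` keeps only the interaction block, ``lm+sl`` keeps interactions
    plus lncRNA similarity, ``lm+sm`` interactions plus miRNA similarity,
    ``none`` returns the full bilayer unchanged.  Used to compare link
    predictability across information sources on the same data.
    """
    if mode not in ABLATION_MODES:
        raise ValueError(f"unknown ablation mode {mode!r}; use {ABLATION_MODES}")
    if mode == "none":
        return net
    a = net.a.copy()
    m = net.m
    if mode in ("lm", "lm+sm"):
        a[:m, :m] = 0.0
    if mode in ("lm", "lm+sl"):
        a[m:, m:] = 0.0
    return BilayerNetwork(net.lnc_ids, net.mi_ids, a)
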