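"""Bilayer network assembly and edge-set perturbation splits.

The bilayer network stacks the lncRNA similarity matrix SL, the miRNA
similarity matrix SM and the binary interaction matrix LM into one
symmetric block matrix::

    A = [ SL   LM ]
        [ LM'  SM ]

of size N = m + n.  A is treated as a weighted graph whose edges are the
unordered node pairs (i, j), i < j, with A(i, j) != 0; a perturbation split
removes a random fraction of those edges into A_p, leaving A_r = A - A_p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix

SYMMETRY_TOL = 1e-12

EDGE_POOLS = ("all_edges", "interaction_edges_only")


@dataclass
class InteractionNetwork:
    """Binary m x n lncRNA-miRNA adjacency matrix with id registries."""

    lnc_ids: list[str]
    mi_ids: list[str]
    lm: np.ndarray

    def __post_init__(self) -> None:
        self.lnc_ids = list(self.lnc_ids)
        self.mi_ids = list(self.mi_ids)
        self.lm = np.asarray(self.lm, dtype=float)
        if len(set(self.lnc_ids)) != len(self.lnc_ids):
            raise ValueError("lncRNA ids must be unique")
        if len(set(self.mi_ids)) != len(self.mi_ids):
            raise ValueError("miRNA ids must be unique")
        if not self.lnc_ids or not self.mi_ids:
            raise ValueError("need at least one lncRNA and one miRNA")
        if self.lm.shape != (len(self.lnc_ids), len(self.mi_ids)):
            raise ValueError(
                f"LM shape {self.lm.shape} does not match id counts "
                f"({len(self.lnc_ids)}, {len(self.mi_ids)})"
            )
        if not np.isin(self.lm, (0.0, 1.0)).all():
            raise ValueError("LM entries must be 0 or 1")

    @property
    def m(self) -> int:
        return len(self.lnc_ids)

    @property
    def n(self) -> int:
        return len(self.mi_ids)

    @property
    def interaction_pairs(self) -> np.ndarray:
        """(k, 2) array of (lnc index, mi index) with LM = 1."""
        return np.argwhere(self.lm == 1.0)


@dataclass
class BilayerNetwork:
    """Symmetric N x N block matrix combining SL, SM and LM."""

    lnc_ids: list[str]
    mi_ids: list[str]
    a: np.ndarray

    def __post_init__(self) -> None:
        self.lnc_ids = list(self.lnc_ids)
        self.mi_ids = list(self.mi_ids)
        self.a = np.asarray(self.a, dtype=float)
        big = self.m + self.n
        if self.a.shape != (big, big):
            raise ValueError(f"A shape {self.a.shape} != ({big}, {big})")
        if np.isnan(self.a).any():
            raise ValueError("bilayer matrix contains undefined entries")
        if not np.allclose(self.a, self.a.T, atol=SYMMETRY_TOL, rtol=0.0):
            raise ValueError("bilayer matrix is not symmetric")

    @property
    def m(self) -> int:
        return len(self.lnc_ids)

    @property
    def n(self) -> int:
        return len(self.mi_ids)

    @property
    def size(self) -> int:
        return self.m + self.n

    @property
    def node_ids(self) -> list[str]:
        return self.lnc_ids + self.mi_ids

    @property
    def sl_block(self) -> np.ndarray:
        return self.a[: self.m, : self.m]

    @property
    def sm_block(self) -> np.ndarray:
        return self.a[self.m:, self.m:]

    @property
    def lm_block(self) -> np.ndarray:
        return self.a[: self.m, self.m:]


@dataclass
class PerturbationSplit:
    """Partition of a bilayer network's edges into retained / perturbed sets.

    ``a_r + a_p == a`` exactly; the two supports are disjoint; edge lists
    hold unordered node pairs (i < j) in global node indexing.
    """

    net: BilayerNetwork
    a_r: np.ndarray
    a_p: np.ndarray
    e_r: np.ndarray
    e_p: np.ndarray
    seed: int
    edge_pool: str = "all_edges"
    fraction: float = 0.1


def align_interactions(
    net: InteractionNetwork, lnc_ids: list[str], mi_ids: list[str]
) -> InteractionNetwork:
    """Re-register an interaction network onto given id universes.

    Edge lists only mention RNAs that have at least one link; similarity
    matrices carry the full universe.  This re-maps LM onto the target
    registries (isolated RNAs become all-zero rows/columns) and errors on
    links whose RNA is absent from the target universe.
    """
    li = {x: i for i, x in enumerate(lnc_ids)}
    mj = {x: j for j, x in enumerate(mi_ids)}
    missing = (set(net.lnc_ids) - li.keys()) | (set(net.mi_ids) - mj.keys())
    if missing:
        raise ValueError(
            f"interacting RNAs absent from the target id universe: "
            f"{sorted(missing)}"
        )
    lm = np.zeros((len(lnc_ids), len(mi_ids)))
    for i, j in net.interaction_pairs:
        lm[li[net.lnc_ids[i]], mj[net.mi_ids[j]]] = 1.0
    return InteractionNetwork(list(lnc_ids), list(mi_ids), lm)


def build_bilayer(
    sl: SimilarityMatrix, sm: SimilarityMatrix, lm: InteractionNetwork
) -> BilayerNetwork:
    """Assemble the symmetric bilayer matrix A from SL, SM and LM."""
    if sl.ids != lm.lnc_ids:
        raise ValueError("SL ids do not match interaction lncRNA ids")
    if sm.ids != lm.mi_ids:
        raise ValueError("SM ids do not match interaction miRNA ids")
    if np.isnan(sl.values).any() or np.isnan(sm.values).any():
        raise ValueError("similarity matrices must be fully defined "
                         "(integrate with sequence similarity first)")
    m, n = lm.m, lm.n
    a = np.zeros((m + n, m + n))
    a[:m, :m] = sl.values
    a[m:, m:] = sm.values
    a[:m, m:] = lm.lm
    a[m:, :m] = lm.lm.T
    return BilayerNetwork(lm.lnc_ids, lm.mi_ids, a)


def edge_pool_pairs(
    net: BilayerNetwork,
    edge_pool: str = "all_edges",
    weight_threshold: float = 0.0,
) -> np.ndarray:
    """Unordered node pairs (i < j) forming the perturbable edge pool.

    ``all_edges`` takes every off-diagonal nonzero of A (optionally above a
    weight threshold); ``interaction_edges_only`` restricts to known
    lncRNA-miRNA links.  Diagonal self-similarities are never edges.
    """
    if edge_pool not in EDGE_POOLS:
        raise ValueError(f"unknown edge pool {edge_pool!r}; use {EDGE_POOLS}")
    if edge_pool == "interaction_edges_only":
        pairs = np.argwhere(net.lm_block != 0.0)
        pairs[:, 1] += net.m
        return pairs
    iu, ju = np.triu_indices(net.size, k=1)
    keep = np.abs(net.a[iu, ju]) > weight_threshold
    return np.column_stack([iu[keep], ju[keep]])


def sample_perturbation_split(
    net: BilayerNetwork,
    fraction: float = 0.1,
    seed: int = 0,
    edge_pool: str = "all_edges",
    weight_threshold: float = 0.0,
) -> PerturbationSplit:
    """Randomly move ``round(fraction * |pool|)`` edges of A into A_p.

    Deterministic for a given seed; ``a_r + a_p == a`` holds exactly by
    construction and the diagonal is never sampled.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    pool = edge_pool_pairs(net, edge_pool, weight_threshold)
    if len(pool) == 0:
        raise ValueError("empty edge pool: no perturbable edges")
    n_pert = int(round(fraction * len(pool)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_pert, replace=False)
    chosen_mask = np.zeros(len(pool), dtype=bool)
    chosen_mask[chosen] = True
    e_p = pool[chosen_mask]
    e_r = pool[~chosen_mask]
    a_r = net.a.copy()
    if len(e_p):
        a_r[e_p[:, 0], e_p[:, 1]] = 0.0
        a_r[e_p[:, 1], e_p[:, 0]] = 0.0
    a_p = net.a - a_r
    return PerturbationSplit(
        net=net, a_r=a_r, a_p=a_p, e_r=e_r, e_p=e_p,
        seed=int(seed), edge_pool=edge_pool, fraction=float(fraction),
    )
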