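"""First-order structural perturbation of a symmetric network matrix.

Given a split A = A_r + A_p, the retained matrix is diagonalised,

    A_r = sum_k lambda_k x_k x_k',

and each eigenvalue is shifted by the first-order correction
``delta_k = x_k' A_p x_k`` (eigenvectors are unit-norm) while the
eigenvectors are kept fixed:

    A~ = sum_k (lambda_k + delta_k) x_k x_k'.

When A_r has a repeated (degenerate) eigenvalue, the eigenvectors of that
eigenvalue are only defined up to rotation, so the correction is obtained by
diagonalising the perturbation inside the degenerate subspace: with
H_qj = x_q' A_p x_j over the group's vectors, the eigenpairs of H give the
eigenvalue shifts and the rotation coefficients, and the rotated vectors
replace the originals in the reconstruction.  A group of size one reduces
exactly to the non-degenerate formula.

The entries of A~ score node pairs: the larger the reconstructed value of an
unobserved pair, the more the retained structure "expects" that link.
Prediction averages A~ over t independent random splits to reduce the bias
of any single perturbation-set draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from ._seeds import derive_seed
from .network import BilayerNetwork, PerturbationSplit, sample_perturbation_split

DEGENERACY_TOL_FACTOR = 1e-8


@dataclass
class EigenSystem:
    """Full symmetric eigendecomposition with degeneracy bookkeeping.

    ``groups`` partitions eigenvalue indices (ascending order) into runs
    that are equal within ``tol``; each run of size > 1 is a degenerate
    subspace.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    groups: list[list[int]]
    tol: float


@dataclass
class ScoreMatrix:
    """Perturbed matrix A~ plus the view used for ranking interactions."""

    matrix: np.ndarray
    lnc_ids: list[str]
    mi_ids: list[str]
    t_used: int
    known: np.ndarray | None = None

    @property
    def m(self) -> int:
        return len(self.lnc_ids)

    @property
    def n(self) -> int:
        return len(self.mi_ids)

    @property
    def interaction_scores(self) -> np.ndarray:
        """The m x n lncRNA-miRNA block of A~ (the only block ranked)."""
        return self.matrix[: self.m, self.m:]


def eigendecompose(
    a_r: np.ndarray, tol_factor: float = DEGENERACY_TOL_FACTOR
) -> EigenSystem:
    """Diagonalise a symmetric matrix and group near-equal eigenvalues.

    Eigenvalues a, b land in the same degeneracy group when
    ``|a - b| <= tol_factor * max(1, ||A_r||_2)``; grouping is transitive
    along ascending order.
    """
    a_r = np.asarray(a_r, dtype=float)
    if a_r.ndim != 2 or a_r.shape[0] != a_r.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(a_r, a_r.T, atol=1e-10, rtol=0.0):
        raise ValueError("matrix must be symmetric")
    lam, vec = eigh(a_r)
    spectral_norm = float(np.max(np.abs(lam))) if lam.size else 0.0
    tol = tol_factor * max(1.0, spectral_norm)
    groups: list[list[int]] = []
    current = [0]
    for k in range(1, lam.size):
        if lam[k] - lam[k - 1] <= tol:
            current.append(k)
        else:
            groups.append(current)
            current = [k]
    groups.append(current)
    return EigenSystem(eigenvalues=lam, eigenvectors=vec, groups=groups, tol=tol)


def perturb_matrix(a_r: np.ndarray, a_p: np.ndarray) -> np.ndarray:
    """First-order perturbed reconstruction A~ of A_r + A_p.

    Handles degenerate eigenvalues by diagonalising A_p within each
    degenerate subspace before applying the eigenvalue shifts.
    """
    es = eigendecompose(a_r)
    a_p = np.asarray(a_p, dtype=float)
    lam = es.eigenvalues.copy()
    basis = es.eigenvectors.copy()
    for group in es.groups:
        idx = np.asarray(group)
        xg = es.eigenvectors[:, idx]
        h = xg.T @ a_p @ xg
        h = (h + h.T) / 2.0
        if len(idx) == 1:
            lam[idx] += h[0, 0]
        else:
            shifts, rot = eigh(h)
            basis[:, idx] = xg @ rot
            lam[idx] += shifts
    a_tilde = (basis * lam) @ basis.T
    return (a_tilde + a_tilde.T) / 2.0


def perturb_once(split: PerturbationSplit) -> ScoreMatrix:
    """Score matrix from a single perturbation split."""
    net = split.net
    return ScoreMatrix(
        matrix=perturb_matrix(split.a_r, split.a_p),
        lnc_ids=net.lnc_ids,
        mi_ids=net.mi_ids,
        t_used=1,
        known=net.lm_block != 0.0,
    )


def predict(
    net: BilayerNetwork,
    t: int = 16,
    fraction: float = 0.1,
    seed: int = 0,
    edge_pool: str = "interaction_edges_only",
) -> ScoreMatrix:
    """Average A~ over ``t`` independent perturbation splits.

    Sub-seeds are derived deterministically from the master seed, so the
    whole t-average is reproducible from one integer.  Known training
    interactions are carried along so downstream ranking can mask them.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    acc = np.zeros_like(net.a)
    for r in range(t):
        split = sample_perturbation_split(
            net, fraction=fraction, seed=derive_seed(seed, r),
            edge_pool=edge_pool,
        )
        acc += perturb_matrix(split.a_r, split.a_p)
    acc /= t
    return ScoreMatrix(
        matrix=acc,
        lnc_ids=net.lnc_ids,
        mi_ids=net.mi_ids,
        t_used=int(t),
        known=net.lm_block != 0.0,
    )
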