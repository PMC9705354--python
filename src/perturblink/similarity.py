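"""Similarity networks over lncRNA or miRNA node sets.

Two complementary similarity measures are computed per RNA class and fused:

* **Expression similarity** — the absolute Pearson correlation between two
  expression profiles.  Taking the absolute value of the covariance makes the
  score nonnegative, so strongly anti-correlated profiles score as similar;
  this is deliberate and documented (the score measures co-regulation
  strength, not its sign).
* **Sequence similarity** — a length-normalised global (Needleman-Wunsch)
  alignment score, clipped into [0, 1].

The fused similarity is the elementwise mean of the two where both are
defined.  Expression profiles are frequently missing or constant; for those
pairs the expression score is *undefined* (NaN) and the fused score falls
back to the sequence score alone, so missing data is complemented rather
than halved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

SYMMETRY_TOL = 1e-12

_ALPHABET = "ACGTN"


@dataclass
class SimilarityMatrix:
    """Square symmetric matrix of pairwise similarities in [0, 1].

    Entries may be NaN, meaning *undefined* (e.g. a missing expression
    profile); defined entries must lie in [0, 1], the NaN pattern and the
    values must be symmetric, and the diagonal is exactly 1.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("similarity matrix ids must be unique")
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} ids"
            )
        if not np.allclose(self.values, self.values.T,
                           atol=SYMMETRY_TOL, rtol=0.0, equal_nan=True):
            raise ValueError("similarity matrix is not symmetric")
        defined = ~np.isnan(self.values)
        if np.any(self.values[defined] < 0) or np.any(self.values[defined] > 1):
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.all(np.diag(self.values) == 1.0):
            raise ValueError("similarity diagonal must be exactly 1")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, rna_id: str) -> int:
        return self.ids.index(rna_id)


@dataclass
class ExpressionProfileTable:
    """Expression profiles keyed by RNA id; profiles may be absent.

    All present profiles share the same length ``h`` (number of expression
    attributes, e.g. tissues or conditions); ``h >= 2`` is required for a
    correlation to exist.
    """

    ids: list[str]
    profiles: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("profile ids must be unique")
        self.profiles = {k: np.asarray(v, dtype=float)
                         for k, v in self.profiles.items()}
        unknown = set(self.profiles) - set(self.ids)
        if unknown:
            raise ValueError(f"profiles for unknown ids: {sorted(unknown)}")
        lengths = {v.shape[-1] for v in self.profiles.values()}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent profile lengths: {sorted(lengths)}")

    @property
    def h(self) -> int:
        for v in self.profiles.values():
            return int(v.shape[-1])
        return 0


@dataclass
class SequenceSet:
    """Nucleotide sequences keyed by RNA id.

    Sequences are upper-cased, U is normalised to T and any residue outside
    {A, C, G, T} becomes N (scored as a mismatch against everything).
    """

    ids: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        clean = {}
        for rna_id in self.ids:
            if rna_id not in self.sequences:
                raise ValueError(f"missing sequence for id {rna_id!r}")
            seq = str(self.sequences[rna_id]).upper().replace("U", "T")
            if not seq:
                raise ValueError(f"empty sequence for id {rna_id!r}")
            clean[rna_id] = "".join(c if c in "ACGT" else "N" for c in seq)
        self.sequences = clean


def expression_similarity(profiles: ExpressionProfileTable) -> SimilarityMatrix:
    """Absolute Pearson correlation between expression profiles.

    Pairs where either profile is missing, or has zero variance, get NaN
    (undefined).  The diagonal is forced to 1 for every id, present or not.
    """
    if not profiles.profiles:
        raise ValueError("no expression data")
    if profiles.h < 2:
        raise ValueError("degenerate profile length: h must be >= 2")

    n = len(profiles.ids)
    out = np.full((n, n), np.nan)
    present = [i for i, rna_id in enumerate(profiles.ids)
               if rna_id in profiles.profiles]
    if present:
        mat = np.stack([profiles.profiles[profiles.ids[i]] for i in present])
        with np.errstate(invalid="ignore", divide="ignore"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                corr = np.corrcoef(mat)
        corr = np.atleast_2d(corr)
        sub = np.abs(corr)
        # zero-variance profiles yield NaN rows from corrcoef; keep them NaN
        out[np.ix_(present, present)] = np.clip(sub, 0.0, 1.0)
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(profiles.ids, out)


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a == b and a != "N":
                matrix[a, b] = match
            else:
                matrix[a, b] = mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def sequence_similarity(
    seqs: SequenceSet,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> SimilarityMatrix:
    """Normalised global-alignment similarity between nucleotide sequences.

    The raw Needleman-Wunsch score (match ``+1``, mismatch ``-1``, linear
    gap ``-1`` by default) is divided by ``match * max(len_i, len_j)`` so two
    identical sequences score 1, and negatives are clipped to 0.
    """
    if match <= 0:
        raise ValueError("match score must be positive")
    aligner = _make_aligner(match, mismatch, gap)
    n = len(seqs.ids)
    out = np.eye(n)
    for i in range(n):
        si = seqs.sequences[seqs.ids[i]]
        for j in range(i + 1, n):
            sj = seqs.sequences[seqs.ids[j]]
            raw = aligner.score(si, sj)
            norm = raw / (match * max(len(si), len(sj)))
            out[i, j] = out[j, i] = min(max(norm, 0.0), 1.0)
    return SimilarityMatrix(seqs.ids, out)


def integrate_similarity(
    ps: SimilarityMatrix, qs: SimilarityMatrix
) -> SimilarityMatrix:
    """Fuse an expression and a sequence similarity matrix.

    Elementwise mean where both are defined; where one is undefined the
    other is used unchanged.  Both inputs must carry the same ids in the
    same order.
    """
    if ps.ids != qs.ids:
        diff = sorted(set(ps.ids) ^ set(qs.ids))
        raise ValueError(
            f"id mismatch between similarity matrices; symmetric "
            f"difference: {diff}" if diff else
            "similarity matrices have the same ids in different order"
        )
    both_nan = np.isnan(ps.values) & np.isnan(qs.values)
    if np.any(both_nan):
        raise ValueError("similarity undefined in both inputs for some pair")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fused = np.nanmean(np.stack([ps.values, qs.values]), axis=0)
    np.fill_diagonal(fused, 1.0)
    fused = (fused + fused.T) / 2.0
    return SimilarityMatrix(ps.ids, fused)
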