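"""Cross-validated evaluation of the perturbation predictor.

Known interactions are split into k folds; each fold's positives are
removed from the training adjacency, the bilayer is rebuilt, and the
t-averaged perturbed matrix scores the held-out positives against an equal
number of sampled unobserved pairs.  Ranking quality is summarised by AUC
(the probability that a random positive outscores a random negative) and by
thresholded confusion-matrix metrics:

    FPR = FP / (TN + FP)        TPR = Sen = TP / (TP + FN)
    Spe = TN / (TN + FP)        Pre = TP / (TP + FP)
    Acc = (TP + TN) / total     F1  = 2 * Pre * Sen / (Pre + Sen)

Interaction data carries no experimentally verified negatives, so negatives
are sampled uniformly from unobserved pairs and the decision threshold is
the median evaluated score; both choices are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from ._seeds import derive_seed
from .network import BilayerNetwork, InteractionNetwork
from .similarity import SimilarityMatrix
from .spm import ScoreMatrix, predict

DIRECTIONS = ("mirnas_for_lncrna", "lncrnas_for_mirna")

METRIC_NAMES = ("fpr", "tpr", "spe", "pre", "sen", "acc", "f1")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def compute_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Classification metrics from confusion counts.

    A metric whose denominator is zero is reported as None (undefined),
    never coerced to 0.
    """

    def ratio(num: float, den: float) -> float | None:
        return num / den if den != 0 else None

    sen = ratio(c.tp, c.tp + c.fn)
    pre = ratio(c.tp, c.tp + c.fp)
    if pre is None or sen is None or (pre + sen) == 0:
        f1 = None
    else:
        f1 = 2.0 * pre * sen / (pre + sen)
    return {
        "fpr": ratio(c.fp, c.tn + c.fp),
        "tpr": sen,
        "spe": ratio(c.tn, c.tn + c.fp),
        "pre": pre,
        "sen": sen,
        "acc": ratio(c.tp + c.tn, c.total),
        "f1": f1,
    }


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Wilcoxon-Mann-Whitney statistic.

    Equals the probability that a uniformly chosen positive outscores a
    uniformly chosen negative; tied scores contribute 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative examples")
    ranks = rankdata(scores)
    return float(
        (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


@dataclass
class EvaluationReport:
    """Per-fold and summary metrics from k-fold cross-validation."""

    fold_auc: list[float]
    fold_metrics: list[dict[str, float | None]]
    fold_positives: list[np.ndarray]
    k: int
    t: int
    fraction: float
    neg_ratio: float
    seed: int
    ablate_mode: str = "none"

    def mean(self, name: str) -> float:
        vals = self._values(name)
        return float(np.mean(vals))

    def std(self, name: str) -> float:
        vals = self._values(name)
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def _values(self, name: str) -> list[float]:
        if name == "auc":
            return self.fold_auc
        vals = [m[name] for m in self.fold_metrics if m[name] is not None]
        if not vals:
            raise ValueError(f"metric {name!r} undefined in every fold")
        return vals


def _fold_assignments(
    n_pos: int, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    perm = rng.permutation(n_pos)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def _ablated_bilayer(
    lm: InteractionNetwork,
    sl: SimilarityMatrix | None,
    sm: SimilarityMatrix | None,
    mode: str,
) -> BilayerNetwork:
    m, n = lm.m, lm.n
    a = np.zeros((m + n, m + n))
    if mode in ("none", "lm+sl"):
        if sl is None:
            raise ValueError("SL required for this ablation mode")
        if sl.ids != lm.lnc_ids:
            raise ValueError("SL ids do not match interaction lncRNA ids")
        a[:m, :m] = sl.values
    if mode in ("none", "lm+sm"):
        if sm is None:
            raise ValueError("SM required for this ablation mode")
        if sm.ids != lm.mi_ids:
            raise ValueError("SM ids do not match interaction miRNA ids")
        a[m:, m:] = sm.values
    a[:m, m:] = lm.lm
    a[m:, :m] = lm.lm.T
    return BilayerNetwork(lm.lnc_ids, lm.mi_ids, a)


def cross_validate(
    lm: InteractionNetwork,
    sl: SimilarityMatrix | None,
    sm: SimilarityMatrix | None,
    k: int = 5,
    t: int = 16,
    fraction: float = 0.1,
    seed: int = 0,
    neg_ratio: float = 1.0,
    ablate_mode: str = "none",
) -> EvaluationReport:
    """k-fold cross-validation of the bilayer perturbation predictor.

    Per fold: the fold's positives are zeroed in the training LM, the
    bilayer is rebuilt (with SL/SM blocks per ``ablate_mode``), ``predict``
    produces the t-averaged score matrix, and held-out positives are scored
    against ``neg_ratio`` times as many unobserved pairs sampled with a
    fold-derived seed.  Thresholded metrics use the median evaluated score
    as the cutoff.
    """
    positives = lm.interaction_pairs
    n_pos = len(positives)
    if n_pos == 0:
        raise ValueError("no known interactions to cross-validate")
    if k < 2 or k > n_pos:
        raise ValueError(f"k={k} invalid for {n_pos} positives")
    rng = np.random.default_rng(derive_seed(seed, 0))
    folds = _fold_assignments(n_pos, k, rng)
    neg_pool = np.argwhere(lm.lm == 0.0)
    if len(neg_pool) == 0:
        raise ValueError("no unobserved pairs to sample negatives from")

    fold_auc: list[float] = []
    fold_metrics: list[dict[str, float | None]] = []
    fold_positive_pairs: list[np.ndarray] = []
    for fold_idx, test_idx in enumerate(folds):
        test_pairs = positives[test_idx]
        fold_positive_pairs.append(test_pairs)
        train_lm = lm.lm.copy()
        train_lm[test_pairs[:, 0], test_pairs[:, 1]] = 0.0
        train_net = InteractionNetwork(lm.lnc_ids, lm.mi_ids, train_lm)
        bilayer = _ablated_bilayer(train_net, sl, sm, ablate_mode)
        scores = predict(
            bilayer, t=t, fraction=fraction,
            seed=derive_seed(seed, 1, fold_idx),
            edge_pool="interaction_edges_only",
        )
        block = scores.interaction_scores
        pos_scores = block[test_pairs[:, 0], test_pairs[:, 1]]
        n_neg = int(round(neg_ratio * len(test_pairs)))
        neg_rng = np.random.default_rng(derive_seed(seed, 2, fold_idx))
        neg_sel = neg_rng.choice(len(neg_pool), size=n_neg, replace=False)
        neg_pairs = neg_pool[neg_sel]
        neg_scores = block[neg_pairs[:, 0], neg_pairs[:, 1]]

        all_scores = np.concatenate([pos_scores, neg_scores])
        labels = np.concatenate(
            [np.ones(len(pos_scores), bool), np.zeros(len(neg_scores), bool)]
        )
        fold_auc.append(auc(all_scores, labels))
        cutoff = float(np.median(all_scores))
        predicted = all_scores > cutoff
        counts = ConfusionCounts(
            tp=int(np.sum(predicted & labels)),
            tn=int(np.sum(~predicted & ~labels)),
            fp=int(np.sum(predicted & ~labels)),
            fn=int(np.sum(~predicted & labels)),
        )
        fold_metrics.append(compute_metrics(counts))

    return EvaluationReport(
        fold_auc=fold_auc,
        fold_metrics=fold_metrics,
        fold_positives=fold_positive_pairs,
        k=int(k), t=int(t), fraction=float(fraction),
        neg_ratio=float(neg_ratio), seed=int(seed),
        ablate_mode=ablate_mode,
    )


@dataclass
class RankedCandidates:
    """Descending-score candidate list for one query RNA."""

    query: str
    direction: str
    candidates: list[tuple[str, float]]
    known: list[bool]


def rank_candidates(
    scores: ScoreMatrix,
    query: str,
    direction: str,
    top_k: int | None = None,
    exclude_known: bool = True,
) -> RankedCandidates:
    """Rank candidate partners of a query RNA by predicted score.

    Candidates sort by score descending, ties broken lexicographically on
    the candidate id.  Pairs already known in training are excluded unless
    ``exclude_known`` is False (case-study mode, where the query's own
    interactions were removed before prediction).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}; use {DIRECTIONS}")
    block = scores.interaction_scores
    known = scores.known if scores.known is not None else np.zeros(
        block.shape, dtype=bool
    )
    if direction == "mirnas_for_lncrna":
        if query not in scores.lnc_ids:
            raise KeyError(f"unknown lncRNA id {query!r}")
        idx = scores.lnc_ids.index(query)
        cand_ids = scores.mi_ids
        cand_scores = block[idx, :]
        cand_known = known[idx, :]
    else:
        if query not in scores.mi_ids:
            raise KeyError(f"unknown miRNA id {query!r}")
        idx = scores.mi_ids.index(query)
        cand_ids = scores.lnc_ids
        cand_scores = block[:, idx]
        cand_known = known[:, idx]

    entries = [
        (cid, float(s), bool(kn))
        for cid, s, kn in zip(cand_ids, cand_scores, cand_known)
        if not (exclude_known and kn)
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    if top_k is not None:
        entries = entries[:top_k]
    return RankedCandidates(
        query=query,
        direction=direction,
        candidates=[(cid, s) for cid, s, _ in entries],
        known=[kn for _, _, kn in entries],
    )


def case_study_predict(
    lm: InteractionNetwork,
    sl: SimilarityMatrix | None,
    sm: SimilarityMatrix | None,
    query: str,
    direction: str,
    t: int = 16,
    fraction: float = 0.1,
    seed: int = 0,
    ablate_mode: str = "none",
) -> ScoreMatrix:
    """Predict after removing every known interaction of the query RNA.

    This is the de-novo recovery protocol: the query's links are blinded,
    the network is rebuilt and all of its candidates are scored afresh, so
    ranking should use ``exclude_known=False``.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}; use {DIRECTIONS}")
    blinded = lm.lm.copy()
    if direction == "mirnas_for_lncrna":
        if query not in lm.lnc_ids:
            raise KeyError(f"unknown lncRNA id {query!r}")
        blinded[lm.lnc_ids.index(query), :] = 0.0
    else:
        if query not in lm.mi_ids:
            raise KeyError(f"unknown miRNA id {query!r}")
        blinded[:, lm.mi_ids.index(query)] = 0.0
    blinded_net = InteractionNetwork(lm.lnc_ids, lm.mi_ids, blinded)
    bilayer = _ablated_bilayer(blinded_net, sl, sm, ablate_mode)
    return predict(bilayer, t=t, fraction=fraction, seed=seed,
                   edge_pool="interaction_edges_only")
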