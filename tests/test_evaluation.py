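from fractions import Fraction

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import perturblink as pl
from perturblink.evaluation import _ablated_bilayer


def metrics_oracle(tp, tn, fp, fn):
    """Exact-rational confusion metrics, independent of the package."""

    def frac(num, den):
        return Fraction(num, den) if den else None

    pre = frac(tp, tp + fp)
    sen = frac(tp, tp + fn)
    f1 = None
    if pre is not None and sen is not None and pre + sen > 0:
        f1 = 2 * pre * sen / (pre + sen)
    return {
        "fpr": frac(fp, tn + fp),
        "tpr": sen,
        "spe": frac(tn, tn + fp),
        "pre": pre,
        "sen": sen,
        "acc": frac(tp + tn, tp + tn + fp + fn),
        "f1": f1,
    }


class TestComputeMetrics:
    def test_hand_worked_confusion_table(self):
        got = pl.compute_metrics(pl.ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert got["pre"] == pytest.approx(0.75)
        assert got["sen"] == pytest.approx(0.75)
        assert got["spe"] == pytest.approx(5 / 6)
        assert got["acc"] == pytest.approx(0.8)
        assert got["f1"] == pytest.approx(0.75)

    def test_perfect_classifier(self):
        got = pl.compute_metrics(pl.ConfusionCounts(tp=1, tn=1, fp=0, fn=0))
        assert got["acc"] == 1.0 and got["f1"] == 1.0 and got["fpr"] == 0.0

    def test_zero_denominator_reports_undefined(self):
        got = pl.compute_metrics(pl.ConfusionCounts(tp=0, tn=4, fp=0, fn=2))
        assert got["pre"] is None

    def test_random_tables_match_rational_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 20, size=4))
            got = pl.compute_metrics(pl.ConfusionCounts(tp, tn, fp, fn))
            want = metrics_oracle(tp, tn, fp, fn)
            for name, expected in want.items():
                if expected is None:
                    assert got[name] is None, name
                else:
                    assert got[name] == pytest.approx(
                        float(expected), abs=1e-12
                    ), name

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pl.ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestAuc:
    def test_perfect_separation(self):
        assert pl.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_symmetric_tie_is_half(self):
        assert pl.auc([0.9, 0.9], [1, 0]) == 0.5

    def test_matches_sklearn_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            scores = rng.normal(size=40)
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            assert pl.auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="positive and negative"):
            pl.auc([0.1, 0.2], [1, 1])


class TestCrossValidate:
    def test_folds_partition_known_interactions(self, dataset):
        lm = dataset.interactions
        report = pl.cross_validate(lm, dataset.sl, dataset.sm,
                                   k=5, t=2, seed=3)
        all_pairs = np.concatenate(report.fold_positives)
        assert len(all_pairs) == int(lm.lm.sum())
        seen = {tuple(p) for p in all_pairs}
        expected = {tuple(p) for p in lm.interaction_pairs}
        assert seen == expected

    def test_same_seed_reproduces_report(self, dataset):
        kw = dict(k=3, t=2, seed=9)
        r1 = pl.cross_validate(dataset.interactions, dataset.sl,
                               dataset.sm, **kw)
        r2 = pl.cross_validate(dataset.interactions, dataset.sl,
                               dataset.sm, **kw)
        assert r1.fold_auc == r2.fold_auc
        assert r1.fold_metrics == r2.fold_metrics

    def test_no_leakage_into_training_bilayer(self, dataset, monkeypatch):
        """Each fold's held-out links must be absent from its training LM."""
        captured = []
        real_predict = pl.evaluation.predict

        def spy(net, **kwargs):
            captured.append(net)
            return real_predict(net, **kwargs)

        monkeypatch.setattr(pl.evaluation, "predict", spy)
        report = pl.cross_validate(dataset.interactions, dataset.sl,
                                   dataset.sm, k=4, t=1, seed=2)
        assert len(captured) == 4
        for net, held in zip(captured, report.fold_positives):
            assert not net.lm_block[held[:, 0], held[:, 1]].any()

    def test_too_many_folds_raises(self, dataset):
        n_pos = int(dataset.interactions.lm.sum())
        with pytest.raises(ValueError, match="invalid"):
            pl.cross_validate(dataset.interactions, dataset.sl,
                              dataset.sm, k=n_pos + 1)

    def test_lm_ablation_needs_no_similarities(self, dataset):
        report = pl.cross_validate(dataset.interactions, None, None,
                                   k=3, t=2, seed=1, ablate_mode="lm")
        assert 0.0 <= report.mean("auc") <= 1.0

    def test_missing_similarity_for_full_mode_raises(self, dataset):
        with pytest.raises(ValueError, match="SL required"):
            pl.cross_validate(dataset.interactions, None, dataset.sm,
                              k=3, t=1)


class TestAblatedBilayer:
    def test_blocks_match_mode(self, dataset):
        lm = dataset.interactions
        full = _ablated_bilayer(lm, dataset.sl, dataset.sm, "none")
        np.testing.assert_array_equal(full.sl_block, dataset.sl.values)
        np.testing.assert_array_equal(full.sm_block, dataset.sm.values)
        only_lm = _ablated_bilayer(lm, None, None, "lm")
        assert not only_lm.sl_block.any() and not only_lm.sm_block.any()
        np.testing.assert_array_equal(only_lm.lm_block, lm.lm)


class TestRankCandidates:
    def _scores(self):
        block = np.array([[0.9, 0.1, 0.5], [0.2, 0.2, 0.2]])
        known = np.array([[False, True, False], [False, False, False]])
        full = np.zeros((5, 5))
        full[:2, 2:] = block
        full[2:, :2] = block.T
        return pl.ScoreMatrix(full, ["L0", "L1"], ["M0", "M1", "M2"],
                              t_used=1, known=known)

    def test_dominant_candidate_ranks_first(self):
        ranked = pl.rank_candidates(self._scores(), "L0",
                                    "mirnas_for_lncrna")
        assert ranked.candidates[0][0] == "M0"

    def test_known_pairs_excluded_by_default(self):
        ranked = pl.rank_candidates(self._scores(), "L0",
                                    "mirnas_for_lncrna")
        assert all(cid != "M1" for cid, _ in ranked.candidates)

    def test_case_study_mode_ranks_known_pairs_too(self):
        ranked = pl.rank_candidates(self._scores(), "L0",
                                    "mirnas_for_lncrna",
                                    exclude_known=False)
        assert [cid for cid, _ in ranked.candidates] == ["M0", "M2", "M1"]

    def test_top_k_larger_than_pool_returns_all(self):
        ranked = pl.rank_candidates(self._scores(), "L1",
                                    "mirnas_for_lncrna", top_k=100)
        assert len(ranked.candidates) == 3

    def test_ties_break_on_candidate_id(self):
        ranked = pl.rank_candidates(self._scores(), "L1",
                                    "mirnas_for_lncrna")
        assert [cid for cid, _ in ranked.candidates] == ["M0", "M1", "M2"]

    def test_reverse_direction(self):
        ranked = pl.rank_candidates(self._scores(), "M2",
                                    "lncrnas_for_mirna")
        assert ranked.candidates[0][0] == "L0"

    def test_unknown_query_raises(self):
        with pytest.raises(KeyError, match="nope"):
            pl.rank_candidates(self._scores(), "nope", "mirnas_for_lncrna")


class TestCaseStudy:
    def test_query_links_removed_before_prediction(self, dataset):
        lm = dataset.interactions
        degrees = lm.lm.sum(axis=1)
        query = lm.lnc_ids[int(np.argmax(degrees))]
        scores = pl.case_study_predict(lm, dataset.sl, dataset.sm, query,
                                       "mirnas_for_lncrna", t=2, seed=0)
        row = scores.known[lm.lnc_ids.index(query), :]
        assert not row.any()

    def test_blinded_true_partners_outscore_non_partners(self, dataset):
        lm = dataset.interactions
        degrees = lm.lm.sum(axis=1)
        idx = int(np.argmax(degrees))
        query = lm.lnc_ids[idx]
        partner_mask = lm.lm[idx, :] == 1.0
        diffs = []
        for seed in range(10):
            scores = pl.case_study_predict(
                lm, dataset.sl, dataset.sm, query,
                "mirnas_for_lncrna", t=8, seed=seed,
            )
            row = scores.interaction_scores[idx, :]
            diffs.append(row[partner_mask].mean() - row[~partner_mask].mean())
        assert np.mean(diffs) > 0.0
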