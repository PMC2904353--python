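"""Confusion metrics, stratified reports, structure QA and the interface
sweep."""
import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from mprap import errors
from mprap.accessibility import BurialState
from mprap.evaluation import (
    ConfusionCounts,
    confusion,
    interface_sweep,
    metrics,
    qa_structure,
    real_metrics,
    stratified_report,
)

B, E = BurialState.BURIED, BurialState.EXPOSED


def random_states(rng, n, p=0.5):
    return [B if v else E for v in rng.random(n) < p]


class TestConfusion:
    def test_perfect_agreement(self):
        states = [B] * 5 + [E] * 5
        c = confusion(states, states)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 5, 0)

    def test_complement_predictions(self):
        truth = [B] * 5 + [E] * 5
        pred = [E] * 5 + [B] * 5
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 5, 0, 5)

    def test_matches_direct_tally_oracle(self):
        rng = np.random.default_rng(1)
        pred = random_states(rng, 100)
        truth = random_states(rng, 100)
        c = confusion(pred, truth)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for p, t in zip(pred, truth):
            key = ("t" if p is t else "f") + ("p" if p is B else "n")
            tally[key] += 1
        assert vars(c) == tally

    def test_length_mismatch_rejected(self):
        with pytest.raises(errors.DomainError):
            confusion([B], [B, E])


class TestMetrics:
    @pytest.mark.parametrize("counts,mcc,acc", [
        ((5, 0, 5, 0), 1.0, 1.0),
        ((0, 5, 0, 5), -1.0, 0.0),
        ((3, 1, 2, 2), 4 / math.sqrt(240), 0.625),
    ])
    def test_hand_computed_examples(self, counts, mcc, acc):
        m = metrics(ConfusionCounts(*counts))
        assert m.mcc == pytest.approx(mcc)
        assert m.accuracy == pytest.approx(acc)

    def test_matches_sklearn_oracle_on_random_configurations(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            pred = random_states(rng, int(rng.integers(4, 50)),
                                 rng.uniform(0.2, 0.8))
            truth = random_states(rng, len(pred), rng.uniform(0.2, 0.8))
            ours = metrics(confusion(pred, truth)).mcc
            ref = matthews_corrcoef([s is B for s in truth],
                                    [s is B for s in pred])
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_mcc_invariant_under_joint_label_swap(self):
        rng = np.random.default_rng(2)
        pred, truth = random_states(rng, 60), random_states(rng, 60)
        swap = {B: E, E: B}
        direct = metrics(confusion(pred, truth)).mcc
        swapped = metrics(confusion([swap[s] for s in pred],
                                    [swap[s] for s in truth])).mcc
        one_sided = metrics(confusion([swap[s] for s in pred], truth)).mcc
        assert direct == pytest.approx(swapped)
        assert one_sided == pytest.approx(-direct)

    def test_empty_truth_class_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.sensitivity == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(errors.DomainError):
            metrics(ConfusionCounts())


class TestRealMetrics:
    def test_identity_shift_and_inversion(self):
        truth = np.array([10.0, 30.0, 50.0, 90.0])
        assert real_metrics(truth, truth) == (0.0, pytest.approx(1.0))
        mae, cc = real_metrics(truth + 10.0, truth)
        assert mae == pytest.approx(10.0) and cc == pytest.approx(1.0)
        _, cc = real_metrics(100.0 - truth, truth)
        assert cc == pytest.approx(-1.0)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(errors.DomainError):
            real_metrics([1.0, 2.0], [5.0, 5.0])


class TestStratifiedReport:
    def test_single_region_input_collapses_to_all(self):
        rng = np.random.default_rng(3)
        pred, truth = random_states(rng, 20), random_states(rng, 20)
        rep = stratified_report(pred, truth, z=np.full(20, 5.0))
        assert rep.strata["core"].n == 20
        assert rep.strata["core"].mcc == pytest.approx(rep.strata["all"].mcc)
        assert rep.strata["interface"].n == 0
        assert rep.strata["interface"].mcc is None

    def test_strata_partition_and_match_subset_oracle(self):
        pred = [B, E, B, E, B, E, B, E, B, E, B, E]
        truth = [B, B, B, E, E, E, B, B, E, E, B, E]
        z = [5, -5, 8, 15, -12, 20, 30, -25, 40, 2, 16, 28]
        rep = stratified_report(pred, truth, z=z)
        sizes = [rep.strata[r].n for r in ("core", "interface", "nonmembrane")]
        assert sum(sizes) == rep.strata["all"].n == 12
        for name, idx in [("core", [0, 1, 2, 9]),
                          ("interface", [3, 4, 5, 10]),
                          ("nonmembrane", [6, 7, 8, 11])]:
            sub = metrics(confusion([pred[i] for i in idx],
                                    [truth[i] for i in idx]))
            assert rep.strata[name].mcc == pytest.approx(sub.mcc)

    def test_missing_z_kept_in_all_only(self):
        pred = [B, E, B, E]
        truth = [B, E, E, B]
        rep = stratified_report(pred, truth,
                                z=[5.0, np.nan, np.nan, 30.0])
        assert rep.strata["all"].n == 4
        assert rep.strata["core"].n == 1
        assert rep.strata["nonmembrane"].n == 1

    def test_table_rendering_contains_region_columns(self):
        rng = np.random.default_rng(4)
        pred, truth = random_states(rng, 30), random_states(rng, 30)
        rep = stratified_report(pred, truth,
                                z=rng.uniform(-30, 30, 30))
        text = rep.to_table()
        for col in ("all", "core", "interface", "nonmembrane", "mcc"):
            assert col in text


class TestQaStructure:
    def test_perfect_agreement_not_suspicious(self):
        states = [B, E] * 10
        r = qa_structure(states, states)
        assert r.mcc == 1.0 and not r.suspicious

    def test_permuted_labels_score_near_zero_and_suspicious(self):
        rng = np.random.default_rng(9)
        observed = random_states(rng, 500)
        permuted = [observed[i] for i in rng.permutation(500)]
        r = qa_structure(observed, permuted)
        assert abs(r.mcc) < 0.15
        assert r.suspicious


class TestInterfaceSweep:
    def test_extreme_cutoffs_and_monotonicity(self):
        rng = np.random.default_rng(5)
        pred = rng.uniform(0, 100, 200)
        truth = rng.random(200) < 0.3
        truth[0] = True
        curve = interface_sweep(pred, truth, cutoffs=np.arange(0, 101, 1.0))
        first, last = curve.iloc[0], curve.iloc[-1]
        assert (first.interface_fraction_below,
                first.noninterface_fraction_above) == (0.0, 1.0)
        assert (last.interface_fraction_below,
                last.noninterface_fraction_above) == (1.0, 0.0)
        assert (np.diff(curve["interface_fraction_below"]) >= 0).all()

    def test_no_interface_truth_rejected(self):
        with pytest.raises(errors.MissingDataError):
            interface_sweep([10.0, 20.0], [False, False])
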