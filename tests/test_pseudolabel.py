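"""The selection core: confidence filtering, two-model consensus, the
iterative rejection loop, and the loss assembly — each checked against a
naive per-row reference implementation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudofuse.pseudolabel import (
    LossConfig,
    ProbabilityMatrix,
    ThresholdSchedule,
    confidence_filter,
    consensus_vote,
    iterative_pseudo_label,
    supervised_loss,
    total_loss,
    unsupervised_loss,
)


def random_prob_matrix(n, C=4, seed=0, prefix="s"):
    rng = np.random.default_rng(seed)
    raw = rng.dirichlet(np.ones(C) * 0.5, size=n)
    return ProbabilityMatrix(tuple(f"{prefix}{i}" for i in range(n)), raw)


def naive_filter(probs: ProbabilityMatrix, tau: float):
    """Brute-force per-row loop reference."""
    accepted, rejected = [], []
    for sid, row in zip(probs.sample_ids, probs.values):
        best = 0
        for k in range(1, len(row)):
            if row[k] > row[best]:
                best = k
        if row[best] >= tau:
            accepted.append((sid, best, row[best]))
        else:
            rejected.append(sid)
    return accepted, rejected


def naive_consensus(pa, pb, tau, policy="reject"):
    accepted, rejected = [], []
    for i, sid in enumerate(pa.sample_ids):
        ya, yb = int(np.argmax(pa.values[i])), int(np.argmax(pb.values[i]))
        ca, cb = pa.values[i].max(), pb.values[i].max()
        if ya == yb and max(ca, cb) >= tau:
            accepted.append((sid, ya, max(ca, cb)))
        elif ya != yb and policy == "max_confidence":
            y, c = (ya, ca) if ca >= cb else (yb, cb)
            if c >= tau:
                accepted.append((sid, y, c))
            else:
                rejected.append(sid)
        else:
            rejected.append(sid)
    return accepted, rejected


class TestConfidenceFilter:
    def test_direct_rule(self):
        probs = ProbabilityMatrix(("x",), np.array([[0.99, 0.003, 0.004, 0.003]]))
        accepted, rejected = confidence_filter(probs, 0.98)
        assert rejected == [] and accepted[0].label == 0
        assert accepted[0].confidence == pytest.approx(0.99)

    def test_threshold_boundary_is_inclusive(self):
        probs = ProbabilityMatrix(("x",), np.array([[0.98, 0.01, 0.005, 0.005]]))
        accepted, _ = confidence_filter(probs, 0.98)
        assert len(accepted) == 1  # >= tau, not > tau

    def test_rejection_then_acceptance_at_relaxed_tau(self):
        probs = ProbabilityMatrix(("x",), np.array([[0.97, 0.01, 0.01, 0.01]]))
        assert confidence_filter(probs, 0.98)[0] == []
        assert len(confidence_filter(probs, 0.95)[0]) == 1

    def test_argmax_tie_broken_by_lowest_class(self):
        probs = ProbabilityMatrix(("x",), np.array([[0.0, 0.5, 0.5, 0.0]]))
        accepted, _ = confidence_filter(probs, 0.5)
        assert accepted[0].label == 1

    def test_matches_naive_loop_on_1000_random_rows(self):
        probs = random_prob_matrix(1000, seed=3)
        prev_accepted = set()
        for tau in (0.98, 0.95, 0.90):
            accepted, rejected = confidence_filter(probs, tau)
            ref_acc, ref_rej = naive_filter(probs, tau)
            assert [(r.sample_id, r.label) for r in accepted] == [
                (s, y) for s, y, _ in ref_acc
            ]
            assert rejected == ref_rej
            assert len(accepted) + len(rejected) == len(probs)
            ids = {r.sample_id for r in accepted}
            assert prev_accepted <= ids  # monotone in relaxing tau
            prev_accepted = ids

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sums"):
            ProbabilityMatrix(("x",), np.array([[0.5, 0.1, 0.1, 0.1]]))

    @settings(max_examples=25, deadline=None)
    @given(n=st.integers(1, 50), tau=st.floats(0.3, 1.0), seed=st.integers(0, 1000))
    def test_partition_property(self, n, tau, seed):
        probs = random_prob_matrix(n, seed=seed)
        accepted, rejected = confidence_filter(probs, tau)
        assert {r.sample_id for r in accepted} | set(rejected) == set(probs.sample_ids)
        assert all(r.confidence >= tau for r in accepted)


class TestConsensusVote:
    def test_agreement_above_tau(self):
        pa = ProbabilityMatrix(("x",), np.array([[0.004, 0.003, 0.99, 0.003]]))
        pb = ProbabilityMatrix(("x",), np.array([[0.005, 0.005, 0.985, 0.005]]))
        accepted, _ = consensus_vote(pa, pb, 0.98)
        assert accepted[0].label == 2 and accepted[0].confidence == pytest.approx(0.99)

    def test_disagreement_rejected_regardless_of_confidence(self):
        pa = ProbabilityMatrix(("x",), np.array([[0.0, 0.99, 0.01, 0.0]]))
        pb = ProbabilityMatrix(("x",), np.array([[0.0, 0.01, 0.0, 0.99]]))
        accepted, rejected = consensus_vote(pa, pb, 0.5, disagreement_policy="reject")
        assert accepted == [] and rejected == ["x"]

    def test_disagreement_max_confidence_policy(self):
        pa = ProbabilityMatrix(("x",), np.array([[0.0, 0.99, 0.01, 0.0]]))
        pb = ProbabilityMatrix(("x",), np.array([[0.0, 0.01, 0.0, 0.99]]))
        accepted, _ = consensus_vote(pa, pb, 0.98, disagreement_policy="max_confidence")
        assert len(accepted) == 1 and accepted[0].label == 1

    def test_agreement_below_tau_rejected(self):
        pa = ProbabilityMatrix(("x",), np.array([[0.97, 0.01, 0.01, 0.01]]))
        pb = ProbabilityMatrix(("x",), np.array([[0.96, 0.02, 0.01, 0.01]]))
        _, rejected = consensus_vote(pa, pb, 0.98)
        assert rejected == ["x"]

    def test_matches_naive_loop_on_500_random_pairs(self):
        pa = random_prob_matrix(500, seed=11)
        pb = random_prob_matrix(500, seed=12)
        for policy in ("reject", "max_confidence"):
            accepted, rejected = consensus_vote(pa, pb, 0.9, disagreement_policy=policy)
            ref_acc, ref_rej = naive_consensus(pa, pb, 0.9, policy)
            assert [(r.sample_id, r.label) for r in accepted] == [
                (s, y) for s, y, _ in ref_acc
            ]
            assert rejected == ref_rej

    def test_mean_confidence_rule(self):
        pa = ProbabilityMatrix(("x",), np.array([[0.99, 0.003, 0.004, 0.003]]))
        pb = ProbabilityMatrix(("x",), np.array([[0.95, 0.02, 0.02, 0.01]]))
        accepted, _ = consensus_vote(pa, pb, 0.9, confidence_rule="mean")
        assert accepted[0].confidence == pytest.approx(0.97)

    def test_misaligned_ids_error(self):
        pa = random_prob_matrix(3, seed=0, prefix="a")
        pb = random_prob_matrix(3, seed=0, prefix="b")
        with pytest.raises(ValueError, match="aligned"):
            consensus_vote(pa, pb, 0.9)


def scripted_score_fn(confidences: dict):
    """Model stub with frozen per-sample confidence; argmax always class 0."""

    def score(ids):
        rows = []
        for sid in ids:
            c = confidences[sid]
            rows.append([c] + [(1 - c) / 3] * 3)
        return ProbabilityMatrix(tuple(ids), np.array(rows))

    return score


class TestIterativeLoop:
    def test_hand_traced_rejection_schedule(self):
        """Frozen confidences {0.99×5, 0.96×3, 0.92×2, 0.5×1} under schedule
        [0.98, 0.95, 0.90] must accept (5, 3, 2) and leave 1 rejected."""
        conf = {}
        for i in range(5):
            conf[f"hi{i}"] = 0.99
        for i in range(3):
            conf[f"mid{i}"] = 0.96
        for i in range(2):
            conf[f"lo{i}"] = 0.92
        conf["never"] = 0.5
        merged, ledger = iterative_pseudo_label(
            scripted_score_fn(conf), list(conf), ThresholdSchedule((0.98, 0.95, 0.90))
        )
        assert [r.accepted for r in ledger.rows] == [5, 3, 2]
        assert [r.rejected for r in ledger.rows] == [6, 3, 1]
        assert ledger.final_rejected == 1
        assert len(merged) == 10
        # conservation at every iteration: accepted + rejected = pool size
        pool = 11
        for row in ledger.rows:
            assert row.accepted + row.rejected == pool
            pool = row.rejected

    def test_all_confident_single_iteration(self):
        conf = {f"s{i}": 0.99 for i in range(4)}
        merged, ledger = iterative_pseudo_label(
            scripted_score_fn(conf), list(conf), ThresholdSchedule((0.98, 0.95))
        )
        assert len(ledger.rows) == 1 and ledger.rows[0].rejected == 0
        assert len(merged) == 4

    def test_empty_pool_no_iterations(self):
        hook_calls = []
        merged, ledger = iterative_pseudo_label(
            scripted_score_fn({}), [], ThresholdSchedule(), hook_calls.append
        )
        assert merged == [] and ledger.rows == [] and hook_calls == []

    def test_hook_failure_preserves_partial_ledger(self):
        conf = {f"s{i}": 0.99 for i in range(3)}

        def failing_hook(accepted, iteration):
            raise RuntimeError("retrain failed")

        with pytest.raises(RuntimeError) as excinfo:
            iterative_pseudo_label(
                scripted_score_fn(conf), list(conf), ThresholdSchedule(), failing_hook
            )
        assert excinfo.value.ledger.rows[0].accepted == 3

    def test_schedule_validation(self):
        with pytest.raises(ValueError, match="non-increasing"):
            ThresholdSchedule((0.9, 0.95))
        with pytest.raises(ValueError):
            ThresholdSchedule(())


class TestLosses:
    def test_perfect_prediction_zero_loss(self):
        probs = np.eye(4)[[0, 1, 2, 3]]
        assert supervised_loss(probs, np.arange(4)) == pytest.approx(0.0, abs=1e-11)

    def test_uniform_prediction_is_log_C(self):
        probs = np.full((5, 4), 0.25)
        assert supervised_loss(probs, np.zeros(5, int)) == pytest.approx(np.log(4))

    def test_matches_naive_summation_oracle(self):
        rng = np.random.default_rng(7)
        probs = rng.dirichlet(np.ones(4), size=50)
        labels = rng.integers(0, 4, 50)
        naive = sum(-np.log(probs[i, labels[i]]) for i in range(50)) / 50
        assert supervised_loss(probs, labels) == pytest.approx(naive, abs=1e-10)

    def test_zero_probability_clamped(self):
        probs = np.array([[1.0, 0.0, 0.0, 0.0]])
        loss = supervised_loss(probs, np.array([1]))
        assert np.isfinite(loss) and loss == pytest.approx(-np.log(1e-12))

    def test_unsupervised_empty_set_is_zero(self):
        assert unsupervised_loss(np.zeros((0, 4)), []) == 0.0

    def test_unsupervised_equals_supervised_on_same_labels(self):
        from pseudofuse.pseudolabel import PseudoLabelRecord

        rng = np.random.default_rng(8)
        probs = rng.dirichlet(np.ones(4), size=10)
        labels = rng.integers(0, 4, 10)
        records = [
            PseudoLabelRecord(f"s{i}", int(labels[i]), 0.99) for i in range(10)
        ]
        assert unsupervised_loss(probs, records) == pytest.approx(
            supervised_loss(probs, labels)
        )

    def test_total_loss_lambda_zero(self):
        assert total_loss(1.5, 9.0, LossConfig(lam=0.0)) == 1.5

    def test_total_loss_simple_sum(self):
        assert total_loss(1.0, 2.0, LossConfig(lam=1.0)) == 3.0

    def test_total_loss_linear_ramp(self):
        config = LossConfig(lam=1.0, ramp_epochs=10)
        assert total_loss(1.0, 2.0, config, epoch=5) == pytest.approx(2.0)
        assert total_loss(1.0, 2.0, config, epoch=20) == pytest.approx(3.0)
        assert total_loss(1.0, 2.0, config, epoch=0) == pytest.approx(1.0)
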