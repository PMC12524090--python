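"""Confidence-guided pseudo-labelling: filtering, consensus voting, the
iterative rejection loop, and the semi-supervised loss assembly.

The selection rule is the classic self-training one: an unlabelled sample is
promoted to the training set with label ``argmax p`` only when its softmax
confidence ``max p`` meets the threshold τ of the current iteration.  Samples
rejected at iteration *t* are re-scored at iteration *t+1* (after retraining,
possibly under a relaxed τ); samples still rejected when the schedule is
exhausted are permanently excluded.  With two models, a pseudo-label is
accepted only on agreement of the argmax classes (decision-level fusion); the
disagreement case is configurable and defaults to rejection, which favours
label purity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "ThresholdSchedule",
    "PseudoLabelRecord",
    "LossConfig",
    "ProbabilityMatrix",
    "confidence_filter",
    "consensus_vote",
    "iterative_pseudo_label",
    "supervised_loss",
    "unsupervised_loss",
    "total_loss",
]

_PROB_ATOL = 1e-6


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Per-sample class-probability vectors with aligned sample ids."""

    sample_ids: tuple[str, ...]
    values: np.ndarray  # (n, C)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        ids = tuple(str(s) for s in self.sample_ids)
        if values.ndim != 2 or len(ids) != len(values):
            raise ValueError("values must be (n, C) aligned with sample_ids")
        if len(values):
            if values.min() < -_PROB_ATOL or values.max() > 1 + _PROB_ATOL:
                raise ValueError("probabilities must lie in [0, 1]")
            sums = values.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > _PROB_ATOL):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(f"row {bad} sums to {sums[bad]:.8f}, not 1")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class ThresholdSchedule:
    """Non-increasing confidence thresholds, one per iteration."""

    thresholds: tuple[float, ...] = (0.98, 0.95, 0.90)

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        if not t:
            raise ValueError("schedule needs at least one threshold")
        if any(not (0.0 < x <= 1.0) for x in t):
            raise ValueError("thresholds must be in (0, 1]")
        if any(t[i] < t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("thresholds must be non-increasing")
        object.__setattr__(self, "thresholds", t)

    @property
    def max_iterations(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class PseudoLabelRecord:
    sample_id: str
    label: int
    confidence: float
    iteration: int = 1
    policy: str = "single_model"


@dataclass(frozen=True)
class LossConfig:
    """Weighting of the unsupervised loss term.

    The effective weight is ``lam * min(1, epoch / ramp_epochs)`` when
    ``ramp_epochs > 0`` (a linear ramp), else the constant ``lam``.
    """

    lam: float = 1.0
    ramp_epochs: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError("lam must be finite and >= 0")
        if self.ramp_epochs < 0:
            raise ValueError("ramp_epochs must be >= 0")


def confidence_filter(
    probs: ProbabilityMatrix, tau: float, iteration: int = 1
) -> tuple[list[PseudoLabelRecord], list[str]]:
    """Accept samples whose max softmax probability is >= ``tau``.

    Accepted samples get label ``argmax`` (ties broken toward the lowest
    class index, numpy's argmax convention) and confidence ``max p``; the
    returned lists partition the input ids.
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must be in (0, 1]")
    accepted: list[PseudoLabelRecord] = []
    rejected: list[str] = []
    if len(probs) == 0:
        return accepted, rejected
    conf = probs.values.max(axis=1)
    labels = probs.values.argmax(axis=1)
    for sid, c, y in zip(probs.sample_ids, conf, labels):
        if c >= tau:
            accepted.append(
                PseudoLabelRecord(sid, int(y), float(c), iteration, "single_model")
            )
        else:
            rejected.append(sid)
    return accepted, rejected


def consensus_vote(
    probs_a: ProbabilityMatrix,
    probs_b: ProbabilityMatrix,
    tau: float,
    disagreement_policy: str = "reject",
    confidence_rule: str = "max",
    iteration: int = 1,
) -> tuple[list[PseudoLabelRecord], list[str]]:
    """Two-model decision-level fusion of pseudo-labels.

    On argmax agreement the sample is accepted when the combined confidence
    (``max`` of the two, or ``mean`` under ``confidence_rule='mean'``) meets
    ``tau``.  On disagreement: reject (default), or under
    ``disagreement_policy='max_confidence'`` adopt the more confident model's
    label when that confidence meets ``tau``.
    """
    if probs_a.sample_ids != probs_b.sample_ids:
        raise ValueError("probability matrices are not aligned on sample_ids")
    if disagreement_policy not in ("reject", "max_confidence"):
        raise ValueError(f"unknown disagreement_policy {disagreement_policy!r}")
    if confidence_rule not in ("max", "mean"):
        raise ValueError(f"unknown confidence_rule {confidence_rule!r}")
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must be in (0, 1]")

    accepted: list[PseudoLabelRecord] = []
    rejected: list[str] = []
    for i, sid in enumerate(probs_a.sample_ids):
        ya = int(np.argmax(probs_a.values[i]))
        yb = int(np.argmax(probs_b.values[i]))
        ca = float(probs_a.values[i, ya])
        cb = float(probs_b.values[i, yb])
        if ya == yb:
            conf = max(ca, cb) if confidence_rule == "max" else 0.5 * (ca + cb)
            if conf >= tau:
                accepted.append(PseudoLabelRecord(sid, ya, conf, iteration, "consensus"))
            else:
                rejected.append(sid)
        elif disagreement_policy == "max_confidence":
            y, conf = (ya, ca) if ca >= cb else (yb, cb)
            if conf >= tau:
                accepted.append(PseudoLabelRecord(sid, y, conf, iteration, "consensus"))
            else:
                rejected.append(sid)
        else:
            rejected.append(sid)
    return accepted, rejected


@dataclass
class LedgerRow:
    iteration: int
    threshold: float
    accepted: int
    rejected: int


@dataclass
class IterationLedger:
    """Per-iteration (threshold, accepted, rejected) bookkeeping."""

    rows: list[LedgerRow] = field(default_factory=list)

    def add(self, iteration: int, threshold: float, accepted: int, rejected: int) -> None:
        self.rows.append(LedgerRow(iteration, threshold, accepted, rejected))

    @property
    def total_accepted(self) -> int:
        return sum(r.accepted for r in self.rows)

    @property
    def final_rejected(self) -> int:
        return self.rows[-1].rejected if self.rows else 0

    def to_records(self) -> list[dict]:
        return [
            {
                "iteration": r.iteration,
                "threshold": r.threshold,
                "accepted": r.accepted,
                "rejected": r.rejected,
            }
            for r in self.rows
        ]


def iterative_pseudo_label(
    score_fn: Callable[[Sequence[str]], ProbabilityMatrix],
    pool_ids: Sequence[str],
    schedule: ThresholdSchedule,
    retrain_hook: "Callable[[list[PseudoLabelRecord], int], None] | None" = None,
) -> tuple[list[PseudoLabelRecord], IterationLedger]:
    """Run the iterative rejection loop over an unlabelled pool.

    Iteration *t* scores the currently remaining pool via ``score_fn`` and
    filters at ``schedule.thresholds[t]``; accepted records are handed to
    ``retrain_hook(accepted_this_iteration, iteration)`` (which typically
    merges them into the labelled set and retrains), and the rejected samples
    form the pool of iteration *t+1*.  Stops when the schedule is exhausted
    or the pool empties.  If the hook raises, the partial ledger is attached
    to the exception (``exc.ledger``).
    """
    remaining = list(pool_ids)
    ledger = IterationLedger()
    merged: list[PseudoLabelRecord] = []
    for t, tau in enumerate(schedule.thresholds, start=1):
        if not remaining:
            break
        probs = score_fn(remaining)
        if list(probs.sample_ids) != remaining:
            raise ValueError("score_fn must return probabilities for exactly the remaining pool")
        accepted, rejected = confidence_filter(probs, tau, iteration=t)
        ledger.add(t, tau, len(accepted), len(rejected))
        merged.extend(accepted)
        if accepted and retrain_hook is not None:
            try:
                retrain_hook(accepted, t)
            except Exception as exc:
                exc.ledger = ledger  # type: ignore[attr-defined]
                raise
        remaining = rejected
    return merged, ledger


def _cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if len(probs) != len(labels):
        raise ValueError("probs and labels must align")
    picked = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.mean(np.log(picked)))


def supervised_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy (natural log) over a labelled batch.

    Zero predicted probability for the true class is clamped at 1e-12.
    """
    if len(labels) == 0:
        raise ValueError("supervised loss needs at least one sample")
    return _cross_entropy(probs, labels)


def unsupervised_loss(probs: np.ndarray, records: Iterable[PseudoLabelRecord]) -> float:
    """Mean cross-entropy against pseudo-labels; 0 for an empty set."""
    records = list(records)
    if not records:
        return 0.0
    labels = np.array([r.label for r in records])
    return _cross_entropy(probs, labels)


def total_loss(l_sup: float, l_unsup: float, config: LossConfig, epoch: int = 0) -> float:
    """Combined objective ``L_sup + λ_eff · L_unsup`` with optional linear ramp."""
    if not (np.isfinite(l_sup) and np.isfinite(l_unsup)):
        raise ValueError("losses must be finite")
    lam_eff = config.lam
    if config.ramp_epochs > 0:
        lam_eff *= min(1.0, epoch / config.ramp_epochs)
    return float(l_sup + lam_eff * l_unsup)
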