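"""Confidence filtering, two-model consensus, and the iterative rejection loop.

Builds a small probability matrix by hand, filters it at the standard
threshold schedule (0.98 → 0.95 → 0.90), and shows how a scripted model with
frozen confidences moves samples from "rejected" to "accepted" as the
threshold relaxes.  The ledger printed at the end is the machine-readable
record an experiment keeps of each iteration.
"""

import numpy as np

from pseudofuse import (
    ProbabilityMatrix,
    ThresholdSchedule,
    confidence_filter,
    consensus_vote,
    iterative_pseudo_label,
)

# --- single-model filtering -------------------------------------------------
probs = ProbabilityMatrix(
    ("scan_a", "scan_b", "scan_c"),
    np.array([
        [0.99, 0.004, 0.003, 0.003],   # confident: accepted at any threshold
        [0.96, 0.020, 0.010, 0.010],   # accepted only once tau drops to 0.95
        [0.40, 0.30, 0.20, 0.10],      # never confident enough
    ]),
)
for tau in (0.98, 0.95, 0.90):
    accepted, rejected = confidence_filter(probs, tau)
    print(f"tau={tau}: accepted {[r.sample_id for r in accepted]}, rejected {rejected}")

# --- two-model consensus ----------------------------------------------------
other = ProbabilityMatrix(
    ("scan_a", "scan_b", "scan_c"),
    np.array([
        [0.97, 0.01, 0.01, 0.01],      # agrees on class 0
        [0.02, 0.96, 0.01, 0.01],      # disagrees with model 1
        [0.50, 0.30, 0.10, 0.10],
    ]),
)
accepted, rejected = consensus_vote(probs, other, tau=0.95)
print(f"consensus at tau=0.95: accepted {[r.sample_id for r in accepted]} "
      f"(disagreements are rejected to keep pseudo-labels clean)")

# --- the iterative loop -----------------------------------------------------
confidences = {f"hi{i}": 0.99 for i in range(5)}
confidences.update({f"mid{i}": 0.96 for i in range(3)})
confidences.update({f"lo{i}": 0.92 for i in range(2)})
confidences["hopeless"] = 0.50


def score(ids):
    rows = [[confidences[s]] + [(1 - confidences[s]) / 3] * 3 for s in ids]
    return ProbabilityMatrix(tuple(ids), np.array(rows))


merged, ledger = iterative_pseudo_label(
    score, list(confidences), ThresholdSchedule((0.98, 0.95, 0.90))
)
print(f"\niterative loop accepted {len(merged)} of {len(confidences)} samples:")
for row in ledger.rows:
    print(f"  iteration {row.iteration}: tau={row.threshold}, "
          f"accepted {row.accepted}, rejected {row.rejected}")
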