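"""Statistical evaluation of paired classifiers.

The toolkit a classifier-comparison study needs when the unit of replication
is either a data split (paired accuracies) or an individual test case
(paired correct/incorrect outcomes):

* paired one-tailed *t*-test on per-split accuracy differences,
* normal-approximation binomial proportion confidence interval,
* Cohen's *d* with the pooled standard deviation,
* McNemar's χ² with Yates continuity correction on a 2×2 paired table,
* Cohen's κ chance-corrected agreement on the same table,
* percentile bootstrap of accuracy over per-case correctness flags.

Accuracies are handled on the percent scale throughout, matching how such
results are reported.  Descriptive mean ± SD summaries use the population SD
(÷n); the *t*-test's ``s_d`` uses the sample SD (n−1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedAccuracyTable",
    "TTestResult",
    "ProportionCIResult",
    "EffectSizeResult",
    "ContingencyTable2x2",
    "McNemarResult",
    "KappaResult",
    "BootstrapResult",
    "paired_t_test",
    "binomial_ci",
    "cohens_d",
    "mcnemar_test",
    "cohens_kappa",
    "bootstrap_accuracy",
    "describe",
]


def describe(values) -> tuple[float, float]:
    """Descriptive (mean, population SD) of a vector, percent scale in/out."""
    v = np.asarray(values, dtype=np.float64)
    return float(v.mean()), float(v.std(ddof=0))


@dataclass(frozen=True)
class PairedAccuracyTable:
    """Aligned accuracy vectors (percent) for two methods over the same splits."""

    split_labels: tuple[str, ...]
    accuracies_a: np.ndarray  # baseline
    accuracies_b: np.ndarray  # comparison

    def __post_init__(self) -> None:
        a = np.asarray(self.accuracies_a, dtype=np.float64)
        b = np.asarray(self.accuracies_b, dtype=np.float64)
        if len(a) != len(b) or len(a) != len(self.split_labels):
            raise ValueError("split labels and both accuracy vectors must align")
        if len(a) < 2:
            raise ValueError("need at least 2 paired observations")
        object.__setattr__(self, "split_labels", tuple(self.split_labels))
        object.__setattr__(self, "accuracies_a", a)
        object.__setattr__(self, "accuracies_b", b)

    @property
    def n(self) -> int:
        return len(self.accuracies_a)

    @property
    def differences(self) -> np.ndarray:
        return self.accuracies_b - self.accuracies_a


@dataclass(frozen=True)
class TTestResult:
    mean_diff: float
    sd_diff: float  # sample SD (n-1)
    t: float
    df: int
    p_one_tailed: float


def paired_t_test(table: PairedAccuracyTable) -> TTestResult:
    """One-tailed paired *t*-test of H1: method B's accuracy exceeds A's.

    ``t = d̄ / (s_d / √n)`` with ``s_d`` the sample SD of the differences and
    ``df = n − 1``; the p-value is the upper tail of Student's t.  With zero
    variance the statistic is degenerate: p is reported as a boundary value
    (0 if d̄ > 0, 1 if d̄ < 0, 0.5 if d̄ = 0) with a warning.
    """
    d = table.differences
    n = table.n
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    df = n - 1
    if sd_diff == 0.0:
        warnings.warn("zero variance of differences; p reported as boundary value", RuntimeWarning)
        p = 0.5 if mean_diff == 0 else (0.0 if mean_diff > 0 else 1.0)
        t = 0.0 if mean_diff == 0 else float(np.sign(mean_diff)) * np.inf
        return TTestResult(mean_diff, sd_diff, t, df, p)
    t = mean_diff / (sd_diff / np.sqrt(n))
    p = float(sps.t.sf(t, df))
    return TTestResult(mean_diff, sd_diff, float(t), df, p)


@dataclass(frozen=True)
class ProportionCIResult:
    p: float  # proportion on [0, 1]
    n: int
    z: float
    standard_error: float  # on the proportion scale
    lower: float  # percent
    upper: float  # percent


def binomial_ci(p: float, n: int, z: float = 1.96) -> ProportionCIResult:
    """Normal-approximation binomial CI: ``p ± z·√(p(1−p)/n)``.

    ``p`` enters on the proportion scale; bounds are returned on the percent
    scale and are deliberately not clipped to [0, 100] (the closed-form
    arithmetic is preserved even near the boundaries).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    se = float(np.sqrt(p * (1.0 - p) / n))
    return ProportionCIResult(
        p=p, n=n, z=z, standard_error=se, lower=(p - z * se) * 100.0, upper=(p + z * se) * 100.0
    )


@dataclass(frozen=True)
class EffectSizeResult:
    mean_b: float
    mean_a: float
    sd_b: float
    sd_a: float
    n_b: int
    n_a: int
    pooled_sd: float
    d: float


def cohens_d(
    mean_b: float, sd_b: float, n_b: int, mean_a: float, sd_a: float, n_a: int
) -> EffectSizeResult:
    """Cohen's *d* = (mean_b − mean_a) / S_pooled with the pooled-variance SD
    ``√(((n_b−1)s_b² + (n_a−1)s_a²)/(n_b+n_a−2))`` (at equal n this reduces
    to ``√((s_b²+s_a²)/2)``)."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    if n_a < 2 or n_b < 2:
        raise ValueError("group sizes must be >= 2")
    pooled = np.sqrt(((n_b - 1) * sd_b**2 + (n_a - 1) * sd_a**2) / (n_b + n_a - 2))
    if pooled == 0:
        raise ValueError("pooled SD is zero; d undefined")
    return EffectSizeResult(
        mean_b, mean_a, sd_b, sd_a, n_b, n_a, float(pooled), float((mean_b - mean_a) / pooled)
    )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Paired outcomes of two classifiers on one test set:
    a = both correct, b = baseline wrong / model correct,
    c = baseline correct / model wrong, d = both wrong."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def model_accuracy(self) -> float:
        """Accuracy (percent) of the model under test (rows)."""
        return 100.0 * (self.a + self.b) / self.n

    @property
    def baseline_accuracy(self) -> float:
        return 100.0 * (self.a + self.c) / self.n

    @property
    def model_misclassification_rate(self) -> float:
        return 100.0 * (self.c + self.d) / self.n

    @property
    def baseline_misclassification_rate(self) -> float:
        return 100.0 * (self.b + self.d) / self.n

    @property
    def agreement_rate(self) -> float:
        """Percent of cases where the two classifiers agree (both correct or
        both wrong)."""
        return 100.0 * (self.a + self.d) / self.n


@dataclass(frozen=True)
class McNemarResult:
    chi2: float
    p: float
    b: int
    c: int


def mcnemar_test(table: ContingencyTable2x2) -> McNemarResult:
    """McNemar's test with Yates continuity correction.

    χ² = (max(|b−c|−1, 0))² / (b+c), two-sided p from χ²₁.  The clamp keeps
    the statistic at 0 when b = c.  Requires at least one discordant pair.
    """
    b, c = table.b, table.c
    if b + c == 0:
        raise ValueError("no discordant pairs; McNemar's test undefined")
    num = max(abs(b - c) - 1, 0)
    chi2 = num**2 / (b + c)
    p = float(sps.chi2.sf(chi2, df=1))
    return McNemarResult(float(chi2), p, b, c)


@dataclass(frozen=True)
class KappaResult:
    kappa: "float | None"
    observed_agreement: float
    expected_agreement: float


def cohens_kappa(table: ContingencyTable2x2) -> KappaResult:
    """Cohen's κ on the 2×2 correct/incorrect agreement table.

    p_o = (a+d)/n; p_e from the row/column marginals; κ = (p_o−p_e)/(1−p_e),
    reported as missing (``None``) when p_e = 1.
    """
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    a, b, c, d = table.a, table.b, table.c, table.d
    p_o = (a + d) / n
    row1, row2 = (a + b) / n, (c + d) / n
    col1, col2 = (a + c) / n, (b + d) / n
    p_e = row1 * col1 + row2 * col2
    if p_e == 1.0:
        return KappaResult(None, p_o, p_e)
    return KappaResult(float((p_o - p_e) / (1.0 - p_e)), float(p_o), float(p_e))


@dataclass(frozen=True)
class BootstrapResult:
    median: float  # percent
    ci_lower: float
    ci_upper: float
    se_boot: float  # percent
    n_resamples: int


def bootstrap_accuracy(
    correct_flags, n_resamples: int = 1000, seed: int = 0
) -> BootstrapResult:
    """Percentile bootstrap of accuracy over per-case correctness flags.

    Resamples the flags with replacement to the original size ``B`` times;
    reports the median, the 2.5/97.5 percentiles and the bootstrap standard
    error with the 1/(B−1) variance convention, all on the percent scale.
    Deterministic for a fixed seed.
    """
    flags = np.asarray(correct_flags, dtype=np.float64)
    if flags.ndim != 1 or len(flags) == 0:
        raise ValueError("correct_flags must be a non-empty 1-D vector")
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    rng = np.random.default_rng(seed)
    n = len(flags)
    idx = rng.integers(0, n, size=(n_resamples, n))
    accs = flags[idx].mean(axis=1) * 100.0
    se = float(np.sqrt(np.sum((accs - accs.mean()) ** 2) / (n_resamples - 1)))
    return BootstrapResult(
        median=float(np.median(accs)),
        ci_lower=float(np.percentile(accs, 2.5)),
        ci_upper=float(np.percentile(accs, 97.5)),
        se_boot=se,
        n_resamples=n_resamples,
    )
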