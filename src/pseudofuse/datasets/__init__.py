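"""Published reference results shipped as CSV inputs.

These small tables hold the reported results of a dual-branch semi-supervised
brain-tumor MRI classification study (four classes, 5712 training / 1311 test
images, labelled fractions 90% down to 10%).  They are *inputs* to the
statistical suite — worked examples whose derived statistics (paired mean
differences, binomial confidence intervals, effect sizes, McNemar's χ²) have
known published values — not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..stats import ContingencyTable2x2, PairedAccuracyTable

__all__ = [
    "load_paired_accuracy",
    "paired_table",
    "load_accuracy_ci_inputs",
    "load_effect_size_inputs",
    "load_contingency_table",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_paired_accuracy() -> pd.DataFrame:
    """Supervised and semi-supervised test accuracy (percent) of the two
    branch architectures over nine labelled/unlabelled splits."""
    return _read("mri_ssl_paired_accuracy.csv")


def paired_table(model: str) -> PairedAccuracyTable:
    """Paired (supervised, semi-supervised) accuracy table for one branch;
    ``model`` is ``'custom_cnn'`` or ``'resnet50'``."""
    df = load_paired_accuracy()
    return PairedAccuracyTable(
        tuple(df["split"]),
        df[f"supervised_{model}"].to_numpy(),
        df[f"ssl_{model}"].to_numpy(),
    )


def load_accuracy_ci_inputs() -> pd.DataFrame:
    """Selected-split test accuracies with the fixed test-set size, the
    inputs of the binomial confidence-interval worked examples."""
    return _read("mri_ssl_accuracy_ci.csv")


def load_effect_size_inputs() -> pd.DataFrame:
    """Per-split supervised/semi-supervised accuracy means and SDs (percent),
    the inputs of the Cohen's d worked examples (equal group sizes)."""
    return _read("mri_ssl_effect_sizes.csv")


def load_contingency_table() -> ContingencyTable2x2:
    """2×2 paired-outcome table of the fused model vs. its strongest
    single-network baseline on the 1311-image test set."""
    row = _read("mri_model_contingency.csv").iloc[0]
    return ContingencyTable2x2(
        a=int(row["both_correct"]),
        b=int(row["baseline_wrong_model_correct"]),
        c=int(row["baseline_correct_model_wrong"]),
        d=int(row["both_wrong"]),
    )
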