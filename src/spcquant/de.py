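"""Differential expression on Ln-transformed NSpC with expression ratios.

Per protein, the natural-log NSpC values of the two conditions are
compared by a two-sided two-sample t-test (Student pooled-variance by
default, Welch optionally).  The expression ratio is the ratio of the
*linear* mean NSpC, treatment over control.  p-values are reported
uncorrected (the conventional spreadsheet workflow this reproduces used
a plain α = 0.05 cut); a Benjamini–Hochberg column is emitted alongside
for users who want it.

The quant matrix must be strictly positive — build it from counts with a
pseudocount (0.5 by default upstream) so Ln is defined for proteins
absent from one condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExperimentDesign

DEFAULT_ALPHA = 0.05
DEFAULT_DE_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DESummary:
    n_tested: int
    n_de: int
    n_increased: int
    n_decreased: int


def de_test(
    quant: pd.DataFrame,
    design: ExperimentDesign,
    alpha: float = DEFAULT_ALPHA,
    variant: str = "student",
    control: str | None = None,
    treatment: str | None = None,
    ratio_mode: str = "linear",
) -> pd.DataFrame:
    """Two-sample t-test on Ln(NSpC) per row, plus treatment/control ratios.

    Parameters
    ----------
    quant
        Strictly positive NSpC matrix (rows = proteins, columns = samples).
    design
        Must resolve to exactly two conditions, or name them via
        ``control``/``treatment``.
    variant
        ``student`` (pooled variance) or ``welch``.
    ratio_mode
        ``linear`` — ratio of linear mean NSpC (default); ``geometric``
        — exp of the difference of Ln means.

    Returns a DataFrame indexed by row id with columns
    ``mean_nspc_control``, ``mean_nspc_treatment``, ``ln_mean_control``,
    ``ln_mean_treatment``, ``ratio``, ``t``, ``p``, ``bh_fdr``,
    ``direction``.  Rows where both groups are constant and equal get the
    degenerate convention t = 0, p = 1.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if ratio_mode not in ("linear", "geometric"):
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    names = design.condition_names
    if control is None and treatment is None:
        if len(names) != 2:
            raise ValueError(
                f"design has {len(names)} conditions; name the pairwise contrast "
                "via control=/treatment="
            )
        control, treatment = names
    if control not in names or treatment not in names:
        raise KeyError(f"contrast conditions must be in {names}")

    ctrl_cols = list(design.conditions[control])
    trt_cols = list(design.conditions[treatment])
    X_c = quant[ctrl_cols].to_numpy(float)
    X_t = quant[trt_cols].to_numpy(float)
    if (X_c <= 0).any() or (X_t <= 0).any():
        raise ValueError(
            "quant matrix must be strictly positive for Ln transform; "
            "normalize with a pseudocount"
        )
    ln_c = np.log(X_c)
    ln_t = np.log(X_t)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_val = stats.ttest_ind(
            ln_t, ln_c, axis=1, equal_var=(variant == "student")
        )
    # degenerate rows: zero variance in both groups -> nan from ttest_ind
    degenerate = ~np.isfinite(t_stat)
    equal_means = np.isclose(ln_t.mean(axis=1), ln_c.mean(axis=1))
    t_stat = np.where(degenerate, 0.0, t_stat)
    p_val = np.where(degenerate & equal_means, 1.0, p_val)
    # constant but different groups: infinite evidence, p -> 0
    p_val = np.where(degenerate & ~equal_means, 0.0, p_val)
    t_stat = np.where(degenerate & ~equal_means, np.inf, t_stat)

    mean_c = X_c.mean(axis=1)
    mean_t = X_t.mean(axis=1)
    if ratio_mode == "linear":
        ratio = mean_t / mean_c
    else:
        ratio = np.exp(ln_t.mean(axis=1) - ln_c.mean(axis=1))

    bh = multipletests(p_val, method="fdr_bh")[1]
    significant = p_val <= alpha
    direction = np.where(
        significant & (ratio > 1.0),
        "increased",
        np.where(significant & (ratio < 1.0), "decreased", "unchanged"),
    )
    return pd.DataFrame(
        {
            "mean_nspc_control": mean_c,
            "mean_nspc_treatment": mean_t,
            "ln_mean_control": ln_c.mean(axis=1),
            "ln_mean_treatment": ln_t.mean(axis=1),
            "ratio": ratio,
            "t": t_stat,
            "p": p_val,
            "bh_fdr": bh,
            "direction": direction,
        },
        index=quant.index,
    )


def summarize_de(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> DESummary:
    """Counts of tested / significant / increased / decreased proteins."""
    sig = results["p"] <= alpha
    inc = int((sig & (results["ratio"] > 1.0)).sum())
    dec = int((sig & (results["ratio"] < 1.0)).sum())
    return DESummary(
        n_tested=len(results),
        n_de=int(sig.sum()),
        n_increased=inc,
        n_decreased=dec,
    )
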