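"""NSpC normalization, the replicate-reproducibility filter, and replicate R².

The normalized spectral count of protein k in one sample is

    NSpC_k = (SpC_k / L_k) / sum_i (SpC_i / L_i)

i.e. each protein's spectral count is divided by its sequence length
(longer proteins yield more tryptic peptides, hence more spectra at
equal molar abundance) and then by the sample total of length-normalized
counts, so every sample column sums to 1 and columns are comparable
across runs of different depth.  This is the NSAF measure of the
spectral-counting literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExperimentDesign

logger = logging.getLogger("spcquant")


def compute_nspc(
    counts: pd.DataFrame,
    lengths: Mapping[str, int] | pd.Series,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Length-normalize a SpC matrix per sample column.

    ``pseudocount`` is added to every SpC before normalization; with the
    default 0, proteins at zero count get NSpC 0.  A column whose
    normalization denominator is zero (all-zero counts with pseudocount
    0) raises, naming the sample.  The denominator sums over *all rows of
    the supplied matrix* — pass the filtered matrix to normalize over the
    reproducible set only.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    lengths = pd.Series(lengths, dtype=float)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no length for row id(s): {list(missing[:5])}")
    L = lengths.reindex(counts.index)
    if (L <= 0).any():
        raise ValueError("all lengths must be positive")

    weighted = (counts.astype(float) + pseudocount).div(L, axis=0)
    denom = weighted.sum(axis=0)
    zero_cols = denom.index[denom == 0.0]
    if len(zero_cols):
        raise ValueError(
            f"sample(s) with zero normalization denominator: {list(zero_cols)}"
        )
    return weighted.div(denom, axis=1)


def reproducibility_filter(
    counts: pd.DataFrame,
    design: ExperimentDesign,
    min_spc: int = 2,
) -> list[str]:
    """Row ids observed in *every* replicate of at least one condition.

    A protein is reproducible when some condition has SpC >= ``min_spc``
    in all of its replicates; presence in only a subset of replicates, or
    scattered across conditions, does not qualify.
    """
    if min_spc < 1:
        raise ValueError("min_spc must be >= 1")
    keep = pd.Series(False, index=counts.index)
    for cond, samples in design.conditions.items():
        keep |= (counts[list(samples)] >= min_spc).all(axis=1)
    return list(counts.index[keep])


@dataclass(frozen=True)
class ReplicateR2:
    """Pairwise within-condition replicate concordance on NSpC."""

    pairs: tuple[tuple[str, str, str, float], ...]  # (condition, sample_a, sample_b, r2)
    mean_r2: float


def replicate_r2(
    quant: pd.DataFrame,
    design: ExperimentDesign,
    rows: Sequence[str] | None = None,
) -> ReplicateR2:
    """Squared Pearson correlation for every within-condition replicate pair.

    Computed on linear NSpC over ``rows`` (default: all rows of the
    matrix).  Pairs with a zero-variance column are excluded with a
    warning rather than contributing NaN to the mean.
    """
    sub = quant.loc[list(rows)] if rows is not None else quant
    pairs: list[tuple[str, str, str, float]] = []
    for cond, samples in design.conditions.items():
        for a, b in combinations(samples, 2):
            x = sub[a].to_numpy(float)
            y = sub[b].to_numpy(float)
            if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
                logger.warning(
                    "replicate pair (%s, %s): zero variance, R^2 undefined; excluded",
                    a,
                    b,
                )
                continue
            r = stats.pearsonr(x, y).statistic
            pairs.append((cond, a, b, float(r * r)))
    if not pairs:
        raise ValueError("no replicate pair with defined R^2")
    mean = float(np.mean([p[3] for p in pairs]))
    return ReplicateR2(pairs=tuple(pairs), mean_r2=mean)
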