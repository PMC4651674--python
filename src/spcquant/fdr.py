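"""Target-decoy FDR estimation and filtering at the PSM level.

The decoy database is built by reversing every target protein sequence,
so a decoy match models a random (incorrect) identification.  At each
score threshold the FDR among accepted targets is estimated by the
decoy/target count ratio; q-values are the monotonized minima of that
running ratio, and identifications are kept at q <= 0.01 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PSMRecord

#: Default PSM-level q-value threshold.
DEFAULT_FDR_THRESHOLD = 0.01


@dataclass(frozen=True)
class ScoredPSMSet:
    """PSMs sorted by score descending with a parallel q-value array.

    Ties in score place decoys before targets (the conservative order:
    a tied decoy counts against the targets it ties with).  q-values are
    monotonically non-decreasing along the sorted order.
    """

    psms: tuple[PSMRecord, ...]
    qvalues: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.psms) != len(self.qvalues):
            raise ValueError("psms and qvalues must be parallel")


def compute_qvalues(psms: list[PSMRecord]) -> ScoredPSMSet:
    """Estimate per-PSM q-values by the target-decoy ratio.

    At rank r in descending-score order, FDR(r) = (#decoys in top r) /
    max(1, #targets in top r); q(r) = min over r' >= r of FDR(r').
    Raises if the input contains no target PSM (nothing to estimate
    against).
    """
    if not psms:
        raise ValueError("cannot estimate FDR on an empty PSM list")
    if all(p.is_decoy for p in psms):
        raise ValueError("all PSMs are decoys; no target to estimate FDR against")

    # decoys first on ties: sort key (score desc, decoy-before-target)
    order = sorted(psms, key=lambda p: (-p.score, not p.is_decoy))
    is_decoy = np.array([p.is_decoy for p in order], dtype=bool)
    n_decoy = np.cumsum(is_decoy)
    n_target = np.cumsum(~is_decoy)
    fdr = n_decoy / np.maximum(1, n_target)
    qvalues = np.minimum.accumulate(fdr[::-1])[::-1]
    return ScoredPSMSet(psms=tuple(order), qvalues=tuple(np.clip(qvalues, 0.0, None)))


def filter_at_fdr(
    scored: ScoredPSMSet, threshold: float = DEFAULT_FDR_THRESHOLD
) -> list[PSMRecord]:
    """Return the target PSMs with q <= threshold (inclusive); never decoys."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    return [
        p
        for p, q in zip(scored.psms, scored.qvalues)
        if not p.is_decoy and q <= threshold
    ]


def fdr_filter_psms(
    psms: list[PSMRecord],
    threshold: float = DEFAULT_FDR_THRESHOLD,
    per_sample: bool = True,
) -> tuple[list[PSMRecord], dict[str, int]]:
    """Convenience wrapper: q-values + filter, optionally pooled per sample.

    Search engines conventionally control PSM FDR within one LC-MS/MS
    run, so the default estimates q-values separately inside each
    sample's pooled PSM set.  Returns the passing targets and a summary
    of PSM counts (in / targets / decoys / kept).
    """
    kept: list[PSMRecord] = []
    if per_sample:
        by_sample: dict[str, list[PSMRecord]] = {}
        for p in psms:
            by_sample.setdefault(p.sample_id, []).append(p)
        for sample_psms in by_sample.values():
            kept.extend(filter_at_fdr(compute_qvalues(sample_psms), threshold))
    else:
        kept = filter_at_fdr(compute_qvalues(psms), threshold)
    summary = {
        "psms_in": len(psms),
        "targets_in": sum(not p.is_decoy for p in psms),
        "decoys_in": sum(p.is_decoy for p in psms),
        "targets_kept": len(kept),
    }
    return kept, summary
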