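"""Protein molecular weight and isoelectric point, plus distribution profiles.

The pI is the pH at which a protein's net charge vanishes.  Net charge
is the Henderson–Hasselbalch sum over the two termini and the ionizable
side chains (C, D, E, H, K, R, Y):

    positive charge of a basic group:  1 / (1 + 10^(pH - pKa))
    negative charge of an acidic group: 1 / (1 + 10^(pKa - pH))

The sum is strictly decreasing in pH, so the root is unique and found by
bisection on [0, 14].  The default pKa table is the EMBOSS Pepstats
default set, bundled as data below; alternative sets can be supplied.

Molecular weight is the sum of average residue masses plus one water
(no modification masses); monoisotopic masses are available by flag.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.SeqUtils import molecular_weight as _bio_mw

from .io import STANDARD_AA

logger = logging.getLogger("spcquant")


@dataclass(frozen=True)
class PKaSet:
    """Dissociation constants for the titratable groups of a protein.

    Acidic groups (negative when deprotonated): C-terminus, C, D, E, Y.
    Basic groups (positive when protonated): N-terminus, H, K, R.
    Defaults are the EMBOSS Pepstats values.
    """

    name: str = "EMBOSS"
    n_term: float = 8.6
    c_term: float = 3.6
    acidic: Mapping[str, float] = field(
        default_factory=lambda: {"C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1}
    )
    basic: Mapping[str, float] = field(
        default_factory=lambda: {"H": 6.5, "K": 10.8, "R": 12.5}
    )

    def __post_init__(self) -> None:
        for pka in (self.n_term, self.c_term, *self.acidic.values(), *self.basic.values()):
            if not 0.0 < pka < 14.0:
                raise ValueError(f"pKa {pka} outside (0, 14)")


EMBOSS_PKA = PKaSet()


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    if not set(seq) <= STANDARD_AA:
        for i, aa in enumerate(seq):
            if aa not in STANDARD_AA:
                raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
    return seq


def molecular_weight(sequence: str, monoisotopic: bool = False) -> float:
    """Protein MW in daltons: residue masses plus one water, no modifications."""
    seq = _validate_sequence(sequence)
    return float(_bio_mw(seq, seq_type="protein", monoisotopic=monoisotopic))


def _charge_at(comp: Counter, pH: float, pkas: PKaSet) -> float:
    pos = 1.0 / (1.0 + 10.0 ** (pH - pkas.n_term))
    neg = 1.0 / (1.0 + 10.0 ** (pkas.c_term - pH))
    for aa, pka in pkas.basic.items():
        pos += comp[aa] / (1.0 + 10.0 ** (pH - pka))
    for aa, pka in pkas.acidic.items():
        neg += comp[aa] / (1.0 + 10.0 ** (pka - pH))
    return pos - neg


def net_charge(sequence: str, pH: float, pkas: PKaSet = EMBOSS_PKA) -> float:
    """Net charge of the sequence at the given pH (composition-only)."""
    return _charge_at(Counter(_validate_sequence(sequence)), pH, pkas)


def isoelectric_point(
    sequence: str, pkas: PKaSet = EMBOSS_PKA, tol: float = 1e-4
) -> float:
    """pH where the net charge crosses zero, by bisection on [0, 14].

    Net charge is strictly decreasing in pH (every term is), so the zero
    is unique; at pH 0 the charge is positive and at pH 14 negative for
    any sequence, guaranteeing the bracket.
    """
    comp = Counter(_validate_sequence(sequence))
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _charge_at(comp, mid, pkas) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class DistributionProfile:
    """Binned fractions of one property for two populations on shared edges."""

    bin_edges: tuple[float, ...]
    fractions: Mapping[str, tuple[float, ...]]  # population -> per-bin fraction


def profile_distributions(
    values: Mapping[str, float],
    reference: Mapping[str, float],
    bin_edges: Sequence[float],
) -> DistributionProfile:
    """Per-bin fractions of two populations (e.g. identified vs whole proteome).

    Values falling outside the outermost edges are clamped into the end
    bins with a warning; each population's fractions sum to 1.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be >= 2 strictly increasing values")

    fractions: dict[str, tuple[float, ...]] = {}
    for name, pop in (("values", values), ("reference", reference)):
        arr = np.fromiter(pop.values(), dtype=float, count=len(pop))
        if arr.size == 0:
            raise ValueError(f"population {name!r} is empty")
        n_out = int(((arr < edges[0]) | (arr > edges[-1])).sum())
        if n_out:
            logger.warning(
                "%d value(s) in %s outside [%g, %g]; clamped into end bins",
                n_out,
                name,
                edges[0],
                edges[-1],
            )
            arr = np.clip(arr, edges[0], edges[-1])
        hist, _ = np.histogram(arr, bins=edges)
        fractions[name] = tuple((hist / arr.size).tolist())
    return DistributionProfile(bin_edges=tuple(edges.tolist()), fractions=fractions)
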