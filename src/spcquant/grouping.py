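"""Protein grouping on shared peptide evidence and spectral counting.

Shotgun identifications are peptide-level; proteins that cannot be
distinguished by the observed peptides are reported as one group:

* accessions with identical observed peptide sets merge;
* an accession whose peptide set is a strict subset of another's is
  subsumed into that protein's group;
* everything else stands alone.

Spectral counts are *redundant*: a PSM whose peptide maps to several
groups increments every one of them, so the column total can exceed the
number of PSMs whenever peptides are shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import ExperimentDesign, PSMRecord, ProteinRecord


@dataclass(frozen=True)
class ProteinGroup:
    """A set of accessions indistinguishable (or subsumable) on observed peptides.

    ``length`` is the representative member's sequence length, the L_k
    used for NSpC normalization; it is None when no sequence database was
    supplied.
    """

    group_id: str
    members: frozenset[str]
    peptide_set: frozenset[str]
    representative: str
    length: int | None = None

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_set)


def _representative(
    members: Iterable[str],
    peptides_of: Mapping[str, frozenset[str]],
    db: Mapping[str, ProteinRecord] | None,
) -> str:
    """Most distinct peptides, then greater sequence length, then accession."""

    def key(acc: str) -> tuple:
        n_pep = len(peptides_of[acc])
        length = db[acc].length if db is not None and acc in db else 0
        return (-n_pep, -length, acc)

    return min(members, key=key)


def group_proteins(
    psms: Sequence[PSMRecord],
    db: Mapping[str, ProteinRecord] | None = None,
    require_lengths: bool = False,
) -> list[ProteinGroup]:
    """Group target accessions by identical/subset observed-peptide sets.

    ``psms`` should already be FDR-filtered targets.  When *db* is given,
    representatives get their sequence length attached (and length breaks
    representative ties); with ``require_lengths`` an accession missing
    from the database is an error.
    """
    peptides_of: dict[str, set[str]] = {}
    for psm in psms:
        if psm.is_decoy:
            continue
        for acc in psm.proteins:
            peptides_of.setdefault(acc, set()).add(psm.peptide)
    frozen = {acc: frozenset(peps) for acc, peps in peptides_of.items()}

    if require_lengths:
        if db is None:
            raise ValueError("require_lengths=True but no sequence database supplied")
        missing = sorted(set(frozen) - set(db))
        if missing:
            raise KeyError(f"accession(s) absent from the sequence database: {missing}")

    # distinct peptide sets; maximal = not a strict subset of any other set
    distinct: dict[frozenset[str], list[str]] = {}
    for acc in sorted(frozen):  # sorted for order-independence of output
        distinct.setdefault(frozen[acc], []).append(acc)
    sets = list(distinct)
    maximal = [
        s for s in sets if not any(s < other for other in sets)
    ]

    # choose, for every non-maximal set, the maximal superset it is absorbed by:
    # the largest superset, ties broken by the representative ordering
    def superset_key(s: frozenset[str]) -> tuple:
        rep = _representative(distinct[s], frozen, db)
        return (-len(s), rep)

    absorbed: dict[frozenset[str], list[str]] = {s: [] for s in maximal}
    for s in sets:
        if s in absorbed:
            continue
        target = min((m for m in maximal if s < m), key=superset_key)
        absorbed[target].extend(distinct[s])

    groups: list[ProteinGroup] = []
    for s in maximal:
        members = frozenset(distinct[s] + absorbed[s])
        rep = _representative(members, frozen, db)
        length = db[rep].length if db is not None and rep in db else None
        groups.append(
            ProteinGroup(
                group_id=rep,
                members=members,
                peptide_set=s,
                representative=rep,
                length=length,
            )
        )
    groups.sort(key=lambda g: g.group_id)
    return groups


def spectral_count_matrix(
    psms: Sequence[PSMRecord],
    groups: Sequence[ProteinGroup],
    design: ExperimentDesign,
) -> pd.DataFrame:
    """Integer SpC per group x sample, counting shared PSMs redundantly.

    Each PSM increments every group containing any of its candidate
    accessions, in its sample's column.  Counts are PSM (spectrum)
    counts, not distinct-peptide counts.  A sample id outside the design
    is an error.
    """
    group_of_acc: dict[str, set[str]] = {}
    for g in groups:
        for acc in g.members:
            group_of_acc.setdefault(acc, set()).add(g.group_id)

    samples = list(design.samples)
    counts = pd.DataFrame(
        0, index=[g.group_id for g in groups], columns=samples, dtype=int
    )
    sample_set = set(samples)
    for psm in psms:
        if psm.is_decoy:
            continue
        if psm.sample_id not in sample_set:
            raise KeyError(f"PSM sample {psm.sample_id!r} not in the experiment design")
        hit_groups: set[str] = set()
        for acc in psm.proteins:
            if acc not in group_of_acc:
                raise KeyError(f"PSM accession {acc!r} maps to no protein group")
            hit_groups |= group_of_acc[acc]
        for gid in hit_groups:
            counts.at[gid, psm.sample_id] += 1
    return counts


def write_groups(groups: Sequence[ProteinGroup], path) -> None:
    rows = [
        {
            "group_id": g.group_id,
            "members": ";".join(sorted(g.members)),
            "representative": g.representative,
            "length": g.length if g.length is not None else "",
            "n_peptides": g.n_peptides,
        }
        for g in groups
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
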