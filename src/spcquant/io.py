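"""Domain types and file I/O for the spectral-counting pipeline.

The pipeline consumes four kinds of input:

* PSM tables — one row per peptide-spectrum match, in a tab-separated
  dialect defined here (search engines export proprietary formats, so a
  plain-text dialect is the portable interchange point);
* a protein sequence database in FASTA;
* a GO annotation table (protein -> term, assumed ancestor-propagated);
* an experiment design (conditions x replicate sample ids), in YAML.

All readers are strict: malformed rows raise with a line number rather
than being silently dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO

logger = logging.getLogger("spcquant")

#: The 20 standard amino acids.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Extended IUPAC one-letter amino-acid codes accepted in FASTA input
#: (standard residues plus ambiguity codes and the rare translated residues).
EXTENDED_AA = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO")

#: Accession prefix marking reversed-sequence decoy entries.
DEFAULT_DECOY_PREFIX = "rev_"

_GO_ID_RE = re.compile(r"^GO:\d{7}$")
_ONTOLOGIES = frozenset("PCF")


class FormatError(ValueError):
    """A structural problem with an input file (missing column, bad header)."""


class RowError(ValueError):
    """A problem with a single data row; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match — the unit of target-decoy FDR control.

    A PSM is a decoy iff *every* candidate parent accession is a decoy
    entry; a peptide that could come from either a target or a decoy
    protein counts as a target observation.
    """

    sample_id: str
    spectrum_id: str
    peptide: str
    proteins: tuple[str, ...]
    score: float
    is_decoy: bool

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("PSM peptide must be non-empty")
        bad = set(self.peptide) - STANDARD_AA
        if bad:
            raise ValueError(
                f"peptide {self.peptide!r} contains non-standard residues {sorted(bad)}"
            )
        if not self.proteins:
            raise ValueError("PSM must list at least one candidate protein")


@dataclass(frozen=True)
class ProteinRecord:
    """A database protein: accession, sequence, and length L_k used by NSpC."""

    accession: str
    sequence: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GOAnnotation:
    """One protein -> GO term assignment, assumed propagated to ancestors."""

    accession: str
    term_id: str
    ontology: str  # P (process), C (component), F (function)
    description: str = ""

    def __post_init__(self) -> None:
        if not _GO_ID_RE.match(self.term_id):
            raise ValueError(f"malformed GO id {self.term_id!r} (expected GO: + 7 digits)")
        if self.ontology not in _ONTOLOGIES:
            raise ValueError(f"ontology must be one of P/C/F, got {self.ontology!r}")


@dataclass(frozen=True)
class ExperimentDesign:
    """Conditions mapped to ordered replicate sample ids.

    The study design this pipeline targets is two conditions with three
    biological replicates each, but any >=2-replicate layout is accepted.
    """

    conditions: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("design must define at least one condition")
        seen: set[str] = set()
        frozen = {}
        for cond, samples in self.conditions.items():
            samples = tuple(samples)
            if len(samples) < 2:
                raise ValueError(f"condition {cond!r} has {len(samples)} replicate(s); need >= 2")
            dup = seen & set(samples)
            if dup:
                raise ValueError(f"sample ids reused across conditions: {sorted(dup)}")
            if len(set(samples)) != len(samples):
                raise ValueError(f"duplicate sample id within condition {cond!r}")
            seen |= set(samples)
            frozen[cond] = samples
        object.__setattr__(self, "conditions", frozen)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(s for samples in self.conditions.values() for s in samples)

    @property
    def condition_names(self) -> tuple[str, ...]:
        return tuple(self.conditions)

    def condition_of(self, sample_id: str) -> str:
        for cond, samples in self.conditions.items():
            if sample_id in samples:
                return cond
        raise KeyError(f"sample {sample_id!r} not in design")


# ---------------------------------------------------------------------------
# PSM TSV dialect
# ---------------------------------------------------------------------------

PSM_COLUMNS = ("sample_id", "spectrum_id", "peptide", "proteins", "score", "is_decoy")
_REQUIRED_PSM_COLUMNS = ("sample_id", "spectrum_id", "peptide", "proteins", "score")

_TRUTHY = {"1", "true", "yes", "t", "y"}
_FALSY = {"0", "false", "no", "f", "n"}


def _parse_bool(token: str, line: int) -> bool:
    low = token.strip().lower()
    if low in _TRUTHY:
        return True
    if low in _FALSY:
        return False
    raise RowError(f"cannot parse boolean {token!r}", line)


def read_psm_table(path: str | Path, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> list[PSMRecord]:
    """Read a PSM table in the tab-separated dialect.

    Columns (header row required): ``sample_id``, ``spectrum_id``,
    ``peptide``, ``proteins`` (semicolon-separated accessions), ``score``,
    and optionally ``is_decoy``.  Lines starting with ``#`` are comments.
    When ``is_decoy`` is absent, a PSM is flagged decoy iff every candidate
    accession starts with *decoy_prefix*; when present, the column wins.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        lines = handle.read().splitlines()

    header: list[str] | None = None
    records: list[PSMRecord] = []
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if header is None:
            header = [h.strip() for h in fields]
            missing = [c for c in _REQUIRED_PSM_COLUMNS if c not in header]
            if missing:
                raise FormatError(f"{path.name}: missing required column(s) {missing}")
            continue
        row = dict(zip(header, fields))
        try:
            score = float(row["score"])
        except (ValueError, KeyError) as exc:
            raise RowError(f"non-numeric score {row.get('score')!r}", lineno) from exc
        proteins = tuple(p.strip() for p in row["proteins"].split(";") if p.strip())
        if not proteins:
            raise RowError("empty proteins field", lineno)
        if "is_decoy" in row and row["is_decoy"].strip() != "":
            is_decoy = _parse_bool(row["is_decoy"], lineno)
        else:
            is_decoy = all(p.startswith(decoy_prefix) for p in proteins)
        try:
            records.append(
                PSMRecord(
                    sample_id=row["sample_id"].strip(),
                    spectrum_id=row["spectrum_id"].strip(),
                    peptide=row["peptide"].strip().upper(),
                    proteins=proteins,
                    score=score,
                    is_decoy=is_decoy,
                )
            )
        except ValueError as exc:
            raise RowError(str(exc), lineno) from exc

    if header is None:
        raise FormatError(f"{path.name}: no header row found")
    if not records:
        logger.warning("%s: header only, no PSM rows", path.name)
    return records


def write_psm_table(psms: Iterable[PSMRecord], path: str | Path) -> None:
    """Write PSMs in the same dialect ``read_psm_table`` consumes (round-trips)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as out:
        out.write("\t".join(PSM_COLUMNS) + "\n")
        for p in psms:
            out.write(
                "\t".join(
                    [
                        p.sample_id,
                        p.spectrum_id,
                        p.peptide,
                        ";".join(p.proteins),
                        repr(p.score),
                        "1" if p.is_decoy else "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Read a protein FASTA into an accession -> ProteinRecord map.

    The accession is the first whitespace-delimited token of the header;
    the remainder of the header line is kept as the description.  Duplicate
    accessions and residues outside the extended IUPAC amino-acid alphabet
    are errors.
    """
    path = Path(path)
    proteins: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in proteins:
            raise FormatError(f"{path.name}: duplicate accession {acc!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - EXTENDED_AA
        if bad:
            raise FormatError(
                f"{path.name}: record {acc!r} has invalid residues {sorted(bad)}"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        proteins[acc] = ProteinRecord(accession=acc, sequence=seq, description=desc)
    return proteins


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as out:
        for p in proteins:
            header = f">{p.accession}"
            if p.description:
                header += f" {p.description}"
            out.write(header + "\n")
            for i in range(0, len(p.sequence), width):
                out.write(p.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

def read_go_annotations(path: str | Path) -> list[GOAnnotation]:
    """Read a 4-column annotation TSV: accession, term_id, ontology, description.

    Duplicate (accession, term) pairs collapse to one annotation; malformed
    term ids or ontology codes raise with the offending line number.
    """
    path = Path(path)
    out: list[GOAnnotation] = []
    seen: set[tuple[str, str]] = set()
    with path.open(encoding="utf-8") as handle:
        header: list[str] | None = None
        for lineno, raw in enumerate(handle, start=1):
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if header is None:
                header = [h.strip() for h in fields]
                missing = [c for c in ("accession", "term_id", "ontology") if c not in header]
                if missing:
                    raise FormatError(f"{path.name}: missing required column(s) {missing}")
                continue
            row = dict(zip(header, fields))
            key = (row["accession"].strip(), row["term_id"].strip())
            if key in seen:
                continue
            try:
                ann = GOAnnotation(
                    accession=key[0],
                    term_id=key[1],
                    ontology=row["ontology"].strip(),
                    description=row.get("description", "").strip(),
                )
            except ValueError as exc:
                raise RowError(str(exc), lineno) from exc
            seen.add(key)
            out.append(ann)
    return out


def write_go_annotations(annotations: Iterable[GOAnnotation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as out:
        out.write("accession\tterm_id\tontology\tdescription\n")
        for a in annotations:
            out.write(f"{a.accession}\t{a.term_id}\t{a.ontology}\t{a.description}\n")


# ---------------------------------------------------------------------------
# Experiment design config
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> ExperimentDesign:
    """Read a design config: YAML mapping ``conditions: {name: [sample ids]}``."""
    with Path(path).open(encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, dict) or "conditions" not in doc:
        raise FormatError(f"{Path(path).name}: expected a mapping with a 'conditions' key")
    conds = doc["conditions"]
    if not isinstance(conds, dict):
        raise FormatError(f"{Path(path).name}: 'conditions' must map names to sample lists")
    return ExperimentDesign(
        conditions={str(c): tuple(str(s) for s in samples) for c, samples in conds.items()}
    )


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    doc = {"conditions": {c: list(s) for c, s in design.conditions.items()}}
    with Path(path).open("w", encoding="utf-8") as out:
        yaml.safe_dump(doc, out, sort_keys=False)
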