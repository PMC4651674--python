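"""Synthetic shotgun-proteomics experiment generator with known ground truth.

Emulates the structure of a two-condition, three-biological-replicate
anther proteome study: a few thousand proteins of widely varying length,
integer spectral counts whose expectation scales with abundance x length
(longer proteins expose more tryptic peptides), a spiked subset of truly
differential proteins at a stated fold change, peptides shared between
protein pairs, and well-separated target/decoy PSM score distributions
with a fraction of incorrect target matches for FDR calibration.

What it deliberately does *not* model: spectra, retention times,
peptide-property-dependent detectability, or score correlation with
peptide length — the generator tests the counting pipeline, not the
search engine.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ExperimentDesign,
    GOAnnotation,
    PSMRecord,
    ProteinRecord,
    write_design,
    write_fasta,
    write_go_annotations,
    write_psm_table,
)

# Roughly physiological amino-acid frequencies; K+R ~ 11 % so tryptic
# peptides average ~9 residues.
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array(
    [
        0.083, 0.014, 0.054, 0.062, 0.039, 0.072, 0.022, 0.053, 0.058, 0.091,
        0.022, 0.043, 0.050, 0.040, 0.052, 0.066, 0.055, 0.069, 0.013, 0.032,
    ]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

_CLEAVE_RE = re.compile(r"(?<=[KR])")


@dataclass(frozen=True)
class SynthParams:
    """Generator settings; the defaults are the emulated study conditions."""

    n_proteins: int = 2000
    length_range: tuple[int, int] = (60, 3000)  # log-uniform residues
    n_replicates: int = 3
    depth: int = 30000  # expected correct PSMs per sample
    abundance_sigma: float = 1.0  # log-normal(0, sigma) protein abundance
    de_fraction: float = 0.05
    fold_change: float = 8.0
    shared_peptide_fraction: float = 0.1
    target_score: tuple[float, float] = (30.0, 5.0)  # mean, sd
    decoy_score: tuple[float, float] = (15.0, 5.0)
    incorrect_target_fraction: float = 0.1
    overdispersion: float = 0.0  # gamma-Poisson dispersion; 0 = pure Poisson
    conditions: tuple[str, str] = ("control", "treatment")
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.de_fraction, self.shared_peptide_fraction,
                     self.incorrect_target_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth of one generated experiment."""

    abundance: pd.DataFrame  # protein x condition true abundance
    de_directions: Mapping[str, str]  # true-DE accession -> increased/decreased
    psm_correct: tuple[bool, ...]  # parallel to the PSM list
    proteins: Mapping[str, ProteinRecord]
    expected_counts: pd.DataFrame  # protein x condition Poisson mean


@dataclass(frozen=True)
class SyntheticExperiment:
    psms: tuple[PSMRecord, ...]
    proteins: Mapping[str, ProteinRecord]
    annotations: tuple[GOAnnotation, ...]
    design: ExperimentDesign
    truth: SynthTruth


def _random_sequences(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    seqs = []
    for L in lengths:
        seqs.append("".join(rng.choice(_AA, size=int(L), p=_AA_FREQ)))
    return seqs


def tryptic_peptides(sequence: str, min_len: int = 6, max_len: int = 30) -> list[str]:
    """Fully-cleaved tryptic fragments (cut after K/R) in the observable
    length window; falls back to all fragments if none fit."""
    frags = [f for f in _CLEAVE_RE.split(sequence) if f]
    observable = [f for f in frags if min_len <= len(f) <= max_len]
    return observable if observable else frags


def simulate_counts(
    params: SynthParams, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], pd.DataFrame, ExperimentDesign]:
    """Draw the correct-match count matrix without expanding PSM rows.

    Returns (counts protein x sample, abundance protein x condition,
    true-DE directions, expected counts protein x condition, design).
    Used directly by calibration studies where PSM-level detail is not
    needed; ``generate_experiment`` builds on the same draw.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    accessions = [f"SYN{i:05d}" for i in range(n)]
    lo, hi = params.length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(int)

    base = rng.lognormal(mean=0.0, sigma=params.abundance_sigma, size=n)
    n_de = round(params.de_fraction * n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    up = rng.random(n_de) < 0.5

    ctrl_name, trt_name = params.conditions
    abundance = pd.DataFrame(
        {ctrl_name: base, trt_name: base.copy()}, index=accessions
    )
    fc = params.fold_change
    trt = abundance[trt_name].to_numpy()
    trt[de_idx[up]] *= fc
    trt[de_idx[~up]] /= fc
    abundance[trt_name] = trt
    de_directions = {
        accessions[i]: ("increased" if u else "decreased")
        for i, u in zip(de_idx, up)
    }

    design = ExperimentDesign(
        conditions={
            ctrl_name: tuple(f"ctrl_{r + 1}" for r in range(params.n_replicates)),
            trt_name: tuple(f"trt_{r + 1}" for r in range(params.n_replicates)),
        }
    )

    expected = {}
    counts = {}
    for cond in params.conditions:
        w = abundance[cond].to_numpy() * lengths
        lam = params.depth * w / w.sum()
        expected[cond] = lam
        for sample in design.conditions[cond]:
            if params.overdispersion > 0:
                shape = 1.0 / params.overdispersion
                lam_s = rng.gamma(shape, lam / shape)
            else:
                lam_s = lam
            counts[sample] = rng.poisson(lam_s)
    counts_df = pd.DataFrame(counts, index=accessions)[list(design.samples)]
    expected_df = pd.DataFrame(expected, index=accessions)
    # carry lengths on the abundance frame for downstream use
    abundance = abundance.assign(length=lengths)
    return counts_df, abundance, de_directions, expected_df, design


def generate_experiment(params: SynthParams) -> SyntheticExperiment:
    """Generate PSM tables, FASTA, GO annotations, design and truth.

    The identical seed yields byte-identical written files.  If the depth
    is too small to place at least one PSM per condition a warning is
    emitted rather than an error.
    """
    rng = np.random.default_rng(params.seed)
    counts, abundance, de_directions, expected, design = simulate_counts(params, rng)
    accessions = list(counts.index)
    lengths = abundance["length"].to_numpy()

    if (counts.sum(axis=0) == 0).any():
        import logging

        logging.getLogger("spcquant").warning(
            "depth %d left at least one sample with zero PSMs", params.depth
        )

    sequences = _random_sequences(rng, lengths)
    proteins = {
        acc: ProteinRecord(accession=acc, sequence=seq, description="synthetic")
        for acc, seq in zip(accessions, sequences)
    }
    digests = [tryptic_peptides(seq) for seq in sequences]

    # shared peptides: a fraction of each protein's observable peptides gains
    # one extra parent protein
    parents_of: dict[str, tuple[str, ...]] = {}
    for i, acc in enumerate(accessions):
        for pep in digests[i]:
            if pep in parents_of:
                continue  # peptide string collision: first owner wins
            if params.shared_peptide_fraction > 0 and rng.random() < params.shared_peptide_fraction:
                j = int(rng.integers(params.n_proteins))
                if j == i:
                    j = (j + 1) % params.n_proteins
                parents_of[pep] = (acc, accessions[j])
            else:
                parents_of[pep] = (acc,)

    t_mean, t_sd = params.target_score
    d_mean, d_sd = params.decoy_score
    f_inc = params.incorrect_target_fraction

    psms: list[PSMRecord] = []
    correct: list[bool] = []
    for sample in design.samples:
        col = counts[sample].to_numpy()
        scan = 0
        # correct target PSMs
        prot_idx = np.repeat(np.arange(params.n_proteins), col)
        scores = rng.normal(t_mean, t_sd, size=prot_idx.size)
        for k, i in enumerate(prot_idx):
            pep_pool = digests[i]
            pep = pep_pool[int(rng.integers(len(pep_pool)))]
            scan += 1
            psms.append(
                PSMRecord(
                    sample_id=sample,
                    spectrum_id=f"{sample}.{scan:06d}",
                    peptide=pep,
                    proteins=parents_of.get(pep, (accessions[i],)),
                    score=float(scores[k]),
                    is_decoy=False,
                )
            )
            correct.append(True)
        # incorrect target matches: random peptide assigned to a random protein
        n_correct = int(col.sum())
        n_incorrect = round(n_correct * f_inc / (1.0 - f_inc)) if f_inc < 1 else 0
        inc_scores = rng.normal(d_mean, d_sd, size=n_incorrect)
        for k in range(n_incorrect):
            i = int(rng.integers(params.n_proteins))
            pep = "".join(rng.choice(_AA, size=int(rng.integers(7, 20)), p=_AA_FREQ))
            scan += 1
            psms.append(
                PSMRecord(
                    sample_id=sample,
                    spectrum_id=f"{sample}.{scan:06d}",
                    peptide=pep,
                    proteins=(accessions[i],),
                    score=float(inc_scores[k]),
                    is_decoy=False,
                )
            )
            correct.append(False)
        # decoy matches, one per incorrect target in expectation
        dec_scores = rng.normal(d_mean, d_sd, size=n_incorrect)
        for k in range(n_incorrect):
            i = int(rng.integers(params.n_proteins))
            pep_pool = digests[i]
            pep = pep_pool[int(rng.integers(len(pep_pool)))][::-1]
            scan += 1
            psms.append(
                PSMRecord(
                    sample_id=sample,
                    spectrum_id=f"{sample}.{scan:06d}",
                    peptide=pep,
                    proteins=(f"rev_{accessions[i]}",),
                    score=float(dec_scores[k]),
                    is_decoy=True,
                )
            )
            correct.append(False)

    annotations = _annotate(rng, accessions, set(de_directions))

    truth = SynthTruth(
        abundance=abundance,
        de_directions=de_directions,
        psm_correct=tuple(correct),
        proteins=proteins,
        expected_counts=expected,
    )
    return SyntheticExperiment(
        psms=tuple(psms),
        proteins=proteins,
        annotations=tuple(annotations),
        design=design,
        truth=truth,
    )


#: GO term designated enriched among the true-DE proteins.
ENRICHED_TERM = "GO:0009408"  # response to heat


def _annotate(
    rng: np.random.Generator, accessions: Sequence[str], de_ids: set[str]
) -> list[GOAnnotation]:
    """Random annotations over ~30 terms; ENRICHED_TERM concentrates on DE ids."""
    annotations: list[GOAnnotation] = []
    for acc in accessions:
        p_hit = 0.6 if acc in de_ids else 0.03
        if rng.random() < p_hit:
            annotations.append(
                GOAnnotation(acc, ENRICHED_TERM, "P", "response to heat")
            )
    ontologies = ["P", "C", "F"]
    for t in range(30):
        term = f"GO:{7000000 + t:07d}"
        ontology = ontologies[t % 3]
        frac = 0.05 + 0.10 * rng.random()
        hit = rng.random(len(accessions)) < frac
        for acc, h in zip(accessions, hit):
            if h:
                annotations.append(
                    GOAnnotation(acc, term, ontology, f"synthetic term {t}")
                )
    return annotations


def write_experiment(exp: SyntheticExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write the four pipeline inputs plus truth tables; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "psms": outdir / "psms.tsv",
        "fasta": outdir / "proteins.fasta",
        "annotations": outdir / "go_annotations.tsv",
        "design": outdir / "design.yaml",
        "truth_abundance": outdir / "truth_abundance.tsv",
        "truth_de": outdir / "truth_de.tsv",
    }
    write_psm_table(exp.psms, paths["psms"])
    write_fasta(
        [exp.proteins[acc] for acc in sorted(exp.proteins)], paths["fasta"]
    )
    write_go_annotations(exp.annotations, paths["annotations"])
    write_design(exp.design, paths["design"])
    exp.truth.abundance.rename_axis("accession").to_csv(
        paths["truth_abundance"], sep="\t"
    )
    pd.Series(dict(exp.truth.de_directions), name="direction").rename_axis(
        "accession"
    ).sort_index().to_csv(paths["truth_de"], sep="\t")
    return paths


@dataclass(frozen=True)
class RecoveryReport:
    sensitivity: float
    realized_fdr: float
    direction_accuracy: float
    n_true: int
    n_flagged: int


def truth_recovery_report(
    truth: SynthTruth, de_results: pd.DataFrame, alpha: float = 0.05
) -> RecoveryReport:
    """Compare DE calls against the generative truth.

    Sensitivity is over the *testable* true-DE proteins, i.e. those
    present in the DE results (upstream filtering can remove low-count
    spiked proteins).  With no flagged proteins the realized FDR is 0 by
    convention.
    """
    flagged = set(de_results.index[de_results["p"] <= alpha])
    true_ids = set(truth.de_directions) & set(de_results.index)
    tp = flagged & true_ids
    sensitivity = len(tp) / len(true_ids) if true_ids else 0.0
    realized_fdr = len(flagged - set(truth.de_directions)) / len(flagged) if flagged else 0.0
    if tp:
        correct_dir = sum(
            de_results.loc[i, "direction"] == truth.de_directions[i] for i in tp
        )
        direction_accuracy = correct_dir / len(tp)
    else:
        direction_accuracy = 0.0
    return RecoveryReport(
        sensitivity=float(sensitivity),
        realized_fdr=float(realized_fdr),
        direction_accuracy=float(direction_accuracy),
        n_true=len(true_ids),
        n_flagged=len(flagged),
    )
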