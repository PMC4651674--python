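"""End-to-end orchestration: FDR -> grouping -> counts -> NSpC -> filter
-> differential expression -> replicate R² -> GO enrichment -> physchem.

One config drives the whole chain; every stage writes a tab-separated
output and the run ends with a JSON manifest of the counts at each stage
(PSMs in/after FDR, groups, proteins after the reproducibility filter,
DE totals, mean R²).  Reruns with identical inputs and config reproduce
identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import de as de_mod
from . import enrichment as enrich_mod
from . import fdr as fdr_mod
from . import grouping as grouping_mod
from . import physchem as physchem_mod
from . import quantify as quantify_mod
from .io import (
    DEFAULT_DECOY_PREFIX,
    ExperimentDesign,
    read_design,
    read_fasta,
    read_go_annotations,
    read_psm_table,
)

logger = logging.getLogger("spcquant")

#: Fig.-2-style default bin edges: pI in unit-width pH bins, MW in 10-kDa bins
#: with an open-ended top bin.
DEFAULT_PI_EDGES = tuple(float(x) for x in range(3, 14))
DEFAULT_MW_EDGES = tuple([*(x * 10_000.0 for x in range(11)), 1e9])


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, design, thresholds and switches for one pipeline run."""

    psm_tables: tuple[str, ...]
    fasta: str
    design: ExperimentDesign
    outdir: str
    go_annotations: str | None = None
    fdr_threshold: float = 0.01
    min_spc: int = 2
    alpha: float = 0.05
    pseudocount: float = 0.5
    ttest_variant: str = "student"
    quantify_by: str = "group"  # or "accession"
    ratio_mode: str = "linear"
    fdr_per_sample: bool = True
    decoy_prefix: str = DEFAULT_DECOY_PREFIX
    control: str | None = None
    treatment: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.min_spc < 1:
            raise ValueError("min_spc must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.quantify_by not in ("group", "accession"):
            raise ValueError("quantify_by must be 'group' or 'accession'")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML (see README for the layout)."""
    base = Path(path).parent
    with Path(path).open(encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)

    def resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    if "design_file" in doc:
        design = read_design(resolve(doc["design_file"]))
    else:
        design = ExperimentDesign(
            conditions={
                c: tuple(s) for c, s in doc["design"]["conditions"].items()
            }
        )
    thresholds = doc.get("thresholds", {})
    switches = doc.get("switches", {})
    contrast = doc.get("contrast", {})
    return PipelineConfig(
        psm_tables=tuple(resolve(p) for p in doc["psm_tables"]),
        fasta=resolve(doc["fasta"]),
        go_annotations=(
            resolve(doc["go_annotations"]) if doc.get("go_annotations") else None
        ),
        design=design,
        outdir=resolve(doc["outdir"]),
        fdr_threshold=float(thresholds.get("fdr", 0.01)),
        min_spc=int(thresholds.get("min_spc", 2)),
        alpha=float(thresholds.get("alpha", 0.05)),
        pseudocount=float(thresholds.get("pseudocount", 0.5)),
        ttest_variant=str(switches.get("ttest_variant", "student")),
        quantify_by=str(switches.get("quantify_by", "group")),
        ratio_mode=str(switches.get("ratio_mode", "linear")),
        fdr_per_sample=bool(switches.get("fdr_per_sample", True)),
        decoy_prefix=str(switches.get("decoy_prefix", DEFAULT_DECOY_PREFIX)),
        control=contrast.get("control"),
        treatment=contrast.get("treatment"),
        seed=int(doc.get("seed", 0)),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": _config_summary(config), "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].setdefault(name, {})
        return manifest["stages"][name]

    try:
        # --- inputs -----------------------------------------------------
        s = stage("inputs")
        psms = []
        for path in config.psm_tables:
            psms.extend(read_psm_table(path, decoy_prefix=config.decoy_prefix))
        db = read_fasta(config.fasta)
        s["psms_in"] = len(psms)
        s["database_proteins"] = len(db)

        # --- PSM FDR ----------------------------------------------------
        s = stage("fdr")
        kept, summary = fdr_mod.fdr_filter_psms(
            psms, threshold=config.fdr_threshold, per_sample=config.fdr_per_sample
        )
        s.update(summary)
        s["threshold"] = config.fdr_threshold

        # --- grouping + counting ---------------------------------------
        s = stage("grouping")
        groups = grouping_mod.group_proteins(kept, db=db, require_lengths=True)
        if config.quantify_by == "accession":
            groups = [
                grouping_mod.ProteinGroup(
                    group_id=acc,
                    members=frozenset([acc]),
                    peptide_set=g.peptide_set,
                    representative=acc,
                    length=db[acc].length,
                )
                for g in groups
                for acc in sorted(g.members)
            ]
        counts = grouping_mod.spectral_count_matrix(kept, groups, config.design)
        grouping_mod.write_groups(groups, outdir / "groups.tsv")
        counts.rename_axis("id").to_csv(outdir / "counts.tsv", sep="\t")
        s["n_groups"] = len(groups)
        s["n_accessions"] = len({a for g in groups for a in g.members})

        lengths = pd.Series({g.group_id: g.length for g in groups}, dtype=float)

        # --- NSpC over all identified proteins (descriptive) ------------
        nspc_all = quantify_mod.compute_nspc(counts, lengths, pseudocount=0.0)
        nspc_all.rename_axis("id").to_csv(outdir / "nspc_all.tsv", sep="\t")

        # --- reproducibility filter ------------------------------------
        s = stage("filter")
        kept_rows = quantify_mod.reproducibility_filter(
            counts, config.design, min_spc=config.min_spc
        )
        s["n_identified"] = len(counts)
        s["n_reproducible"] = len(kept_rows)
        report = pd.DataFrame(
            {
                "id": counts.index,
                "kept": [i in set(kept_rows) for i in counts.index],
            }
        )
        report.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)

        # --- NSpC on the filtered matrix, R², DE ------------------------
        s = stage("quantification")
        counts_f = counts.loc[kept_rows]
        nspc_f0 = quantify_mod.compute_nspc(counts_f, lengths, pseudocount=0.0)
        nspc_f0.rename_axis("id").to_csv(outdir / "nspc_filtered.tsv", sep="\t")
        r2 = quantify_mod.replicate_r2(nspc_f0, config.design)
        pd.DataFrame(
            [*r2.pairs, ("mean", "", "", r2.mean_r2)],
            columns=["condition", "sample_a", "sample_b", "r2"],
        ).to_csv(outdir / "replicate_r2.tsv", sep="\t", index=False)
        s["mean_r2"] = r2.mean_r2

        s = stage("differential_expression")
        nspc_de = quantify_mod.compute_nspc(
            counts_f, lengths, pseudocount=config.pseudocount
        )
        results = de_mod.de_test(
            nspc_de,
            config.design,
            alpha=config.alpha,
            variant=config.ttest_variant,
            control=config.control,
            treatment=config.treatment,
            ratio_mode=config.ratio_mode,
        )
        results = results.assign(
            description=[db[i].description if i in db else "" for i in results.index]
        )
        results.rename_axis("id").to_csv(outdir / "de_results.tsv", sep="\t")
        de_summary = de_mod.summarize_de(results, alpha=config.alpha)
        s.update(
            n_tested=de_summary.n_tested,
            n_de=de_summary.n_de,
            n_increased=de_summary.n_increased,
            n_decreased=de_summary.n_decreased,
        )

        # --- GO enrichment of the DE list -------------------------------
        if config.go_annotations is not None:
            s = stage("enrichment")
            annotations = read_go_annotations(config.go_annotations)
            de_ids = {
                g
                for gid in results.index[results["p"] <= config.alpha]
                for g in _group_accessions(gid, groups)
            }
            background = {a for g in groups for a in g.members}
            table = enrich_mod.enrich(de_ids, annotations, background)
            table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            s["n_terms_tested"] = len(table)
            s["n_terms_fdr05"] = int((table["fdr"] <= 0.05).sum()) if len(table) else 0

        # --- physicochemical profile ------------------------------------
        s = stage("physchem")
        identified = sorted({g.representative for g in groups})
        rows = []
        for acc in identified:
            seq = _standardize(db[acc].sequence)
            rows.append(
                {
                    "accession": acc,
                    "length": db[acc].length,
                    "mw_da": physchem_mod.molecular_weight(seq),
                    "pi": physchem_mod.isoelectric_point(seq),
                }
            )
        phys = pd.DataFrame(rows)
        phys.to_csv(outdir / "physchem.tsv", sep="\t", index=False)
        ref_pi = {
            acc: physchem_mod.isoelectric_point(_standardize(rec.sequence))
            for acc, rec in db.items()
        }
        prof = physchem_mod.profile_distributions(
            dict(zip(phys["accession"], phys["pi"])), ref_pi, DEFAULT_PI_EDGES
        )
        _write_profile(prof, outdir / "pi_bins.tsv")
        ref_mw = {
            acc: physchem_mod.molecular_weight(_standardize(rec.sequence))
            for acc, rec in db.items()
        }
        prof_mw = physchem_mod.profile_distributions(
            dict(zip(phys["accession"], phys["mw_da"])), ref_mw, DEFAULT_MW_EDGES
        )
        _write_profile(prof_mw, outdir / "mw_bins.tsv")
        s["n_profiled"] = len(phys)
    except Exception as exc:
        stage_name = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise PipelineError(stage_name, exc) from exc

    with (outdir / "manifest.json").open("w", encoding="utf-8") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
        out.write("\n")
    return manifest


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name for CLI exit reporting."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _group_accessions(group_id: str, groups) -> set[str]:
    for g in groups:
        if g.group_id == group_id:
            return set(g.members)
    return {group_id}


_NONSTANDARD = str.maketrans("", "", "BXZJUO")


def _standardize(sequence: str) -> str:
    """Drop ambiguity codes before physchem math (they carry no defined mass/pKa)."""
    return sequence.translate(_NONSTANDARD)


def _write_profile(prof, path) -> None:
    edges = prof.bin_edges
    pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "fraction_identified": prof.fractions["values"],
            "fraction_reference": prof.fractions["reference"],
        }
    ).to_csv(path, sep="\t", index=False)


def _config_summary(config: PipelineConfig) -> dict:
    return {
        "psm_tables": list(config.psm_tables),
        "fasta": config.fasta,
        "go_annotations": config.go_annotations,
        "conditions": {c: list(s) for c, s in config.design.conditions.items()},
        "fdr_threshold": config.fdr_threshold,
        "min_spc": config.min_spc,
        "alpha": config.alpha,
        "pseudocount": config.pseudocount,
        "ttest_variant": config.ttest_variant,
        "quantify_by": config.quantify_by,
        "ratio_mode": config.ratio_mode,
        "fdr_per_sample": config.fdr_per_sample,
        "decoy_prefix": config.decoy_prefix,
        "seed": config.seed,
    }
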