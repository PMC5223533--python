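"""Per-species analysis orchestration and cultivated-vs-wild contrasts.

A run is driven by one YAML config naming the input files per species plus
the analysis parameters (flank width, window size, k, replicate count,
seed, alpha).  Every stage logs record counts in and out, every report
carries a provenance block (config hash, seed, package version), and a
fixed config + seed reproduces byte-identical report files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from . import __version__
from . import io as tio
from .assignment import assign_all, count_by_compartment, family_te_counts
from .compartments import build_compartment_map, compartment_lengths
from .core import GENIC_LABELS, ValidationError
from .density import kmeans_density_clusters, window_te_density, windows_to_frame
from .expression import classify_expressed, stratified_exon_intron_counts
from .stats import (
    chisq_goodness_of_fit,
    expected_genic_proportion,
    fisher_exact,
    fold_difference,
    go_enrichment,
    prop_test_given,
    prop_test_two_sample,
    randomize_te_placements,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for clean aborts."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class SpeciesInputs:
    genes: Path
    tes: Path
    chrom_lengths: Path
    expression: Optional[Path] = None
    gene_terms: Optional[Path] = None
    gene_families: Optional[Path] = None


@dataclass
class RunConfig:
    species: dict[str, SpeciesInputs]
    flank_bp: int = 2000
    window_bp: int = 100_000
    k: int = 3
    n_reps: int = 1000
    seed: int = 0
    alpha: float = 0.05
    correction: bool = True
    groups: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        species = {}
        for sid, paths in (raw.get("species") or {}).items():
            kwargs = {}
            for key in ("genes", "tes", "chrom_lengths", "expression", "gene_terms", "gene_families"):
                if key in paths and paths[key] is not None:
                    kwargs[key] = Path(paths[key])
            for key in ("genes", "tes", "chrom_lengths"):
                if key not in kwargs:
                    raise ValidationError(f"species {sid}: missing required input {key!r}")
            species[sid] = SpeciesInputs(**kwargs)
        cfg = cls(
            species=species,
            flank_bp=int(raw.get("flank_bp", 2000)),
            window_bp=int(raw.get("window_bp", 100_000)),
            k=int(raw.get("k", 3)),
            n_reps=int(raw.get("n_reps", 1000)),
            seed=int(raw.get("seed", 0)),
            alpha=float(raw.get("alpha", 0.05)),
            correction=bool(raw.get("correction", True)),
            groups={k: list(v) for k, v in (raw.get("groups") or {}).items()},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (self.flank_bp >= 0 and self.window_bp >= 1 and self.k >= 1 and self.n_reps >= 1):
            raise ValidationError("parameter out of documented range")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        for sid, inputs in self.species.items():
            for key in ("genes", "tes", "chrom_lengths", "expression", "gene_terms", "gene_families"):
                p = getattr(inputs, key)
                if p is not None and not Path(p).exists():
                    raise ValidationError(f"species {sid}: {key} file not found: {p}")

    def content_hash(self) -> str:
        blob = json.dumps(
            {
                "species": {
                    sid: {k: str(getattr(v, k)) for k in v.__dataclass_fields__ if getattr(v, k)}
                    for sid, v in sorted(self.species.items())
                },
                "flank_bp": self.flank_bp,
                "window_bp": self.window_bp,
                "k": self.k,
                "n_reps": self.n_reps,
                "seed": self.seed,
                "alpha": self.alpha,
                "correction": self.correction,
                "groups": {k: sorted(v) for k, v in sorted(self.groups.items())},
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict[str, Any]:
    return {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
    }


def run_species_analysis(
    config: RunConfig, species_id: str, outdir: Optional[Path | str] = None
) -> dict[str, Any]:
    """Full per-species analysis; returns (and optionally writes) a report.

    Stages: read -> compartments -> assignment -> density -> null + tests ->
    expression strata -> enrichment.  Missing optional inputs degrade
    gracefully (the stage is skipped with a notice in the report).
    """
    if species_id not in config.species:
        raise PipelineError("config", f"unknown species {species_id!r}")
    inputs = config.species[species_id]

    stage = "annotations_io"
    try:
        genes = tio.read_gff3_genes(inputs.genes)
        tes = tio.read_repeatmasker_out(inputs.tes)
        chroms = tio.read_chrom_lengths(inputs.chrom_lengths)
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc))
    logger.info("%s: read %d genes, %d TE copies, %d chromosomes",
                species_id, len(genes), len(tes), len(chroms))

    stage = "genome_compartments"
    try:
        cmap = build_compartment_map(genes, chroms, flank_bp=config.flank_bp)
        clens = compartment_lengths(cmap)
    except ValueError as exc:
        raise PipelineError(stage, str(exc))

    stage = "te_assignment"
    try:
        assignments = assign_all(tes, cmap)
        counts = count_by_compartment(assignments, tes, cmap, species_id=species_id)
    except ValueError as exc:
        raise PipelineError(stage, str(exc))

    stage = "density_landscape"
    windows = window_te_density(tes, assignments, chroms, window_bp=config.window_bp)
    clusters = kmeans_density_clusters(windows, k=min(config.k, len(windows)), seed=config.seed)

    stage = "null_and_stats"
    report: dict[str, Any] = {
        "species_id": species_id,
        "n_genes": len(genes),
        "n_tes": len(tes),
        "compartment_bp": dict(sorted(clens.by_label.items())),
        "genome_total_bp": clens.genome_total,
        "te_genome_fraction": counts.te_genome_fraction,
        "genic_share_primary": counts.genic_share,
        "genic_share_any_overlap": counts.genic_share_any_overlap,
        "flank_copies": sum(
            r.primary_label in ("upstream", "downstream") for r in assignments
        ),
        "provenance": _provenance(config),
        "skipped_stages": [],
    }
    if tes:
        p0 = expected_genic_proportion(clens)
        null = randomize_te_placements(tes, cmap, n_reps=config.n_reps, seed=config.seed)
        genic_k = sum(r.genic for r in assignments)
        depletion = prop_test_given(genic_k, len(tes), p0, correction=config.correction)
        report["null"] = {
            "analytic_expectation": p0,
            "mc_mean": null.mean,
            "mc_sd": null.std,
            "n_reps": null.n_reps,
        }
        report["depletion_test"] = {
            "observed_genic": genic_k,
            "n_tes": len(tes),
            "expected_proportion": p0,
            "observed_over_expected": (genic_k / len(tes)) / p0 if p0 > 0 else None,
            "statistic": depletion.statistic,
            "p_value": depletion.p_value,
            "significant": depletion.p_value <= config.alpha,
            "direction": "depleted" if genic_k / len(tes) < p0 else "enriched",
        }
    else:
        report["skipped_stages"].append("null_and_stats: no TE copies")

    stage = "expression_strata"
    strata = None
    if inputs.expression is not None:
        records = tio.read_expression_table(inputs.expression)
        universe = {g.gene_id for g in genes}
        strata = classify_expressed(records, universe)
        table = stratified_exon_intron_counts(assignments, strata)
        expr_exon = int(table.counts.loc["expressed", "exon"])
        expr_intron = int(table.counts.loc["expressed", "intron"])
        report["strata"] = {
            "n_expressed": len(strata.expressed),
            "n_non_expressed": len(strata.non_expressed),
            "table": table.as_2x2(),
            "genes_with_te": table.genes_with_te,
            "multi_stratum_duplicates": table.n_multi_stratum_duplicates,
        }
        if expr_exon + expr_intron > 0:
            gof = chisq_goodness_of_fit([expr_exon, expr_intron], [0.5, 0.5])
            report["strata"]["exon_intron_chisq"] = gof.statistic
            report["strata"]["exon_intron_chisq_p"] = gof.p_value
            if expr_exon >= 1:
                report["strata"]["intron_exon_fold"] = fold_difference(expr_intron, expr_exon)
        fr = fisher_exact(table.as_2x2())
        report["strata"]["fisher_p"] = fr.p_value
        report["strata"]["fisher_degenerate"] = fr.degenerate
    else:
        report["skipped_stages"].append("expression_strata: no expression table")

    stage = "enrichment"
    if inputs.gene_terms is not None:
        gene_to_terms = tio.read_gene_map(inputs.gene_terms)
        universe = {g.gene_id for g in genes}
        study = {
            g
            for rec in assignments
            if rec.primary_label in GENIC_LABELS
            for g in rec.owner_gene_ids
        } & universe
        if study:
            rows = go_enrichment(study, universe, gene_to_terms)
            report["enrichment"] = [
                {
                    "term_id": r.term_id,
                    "k": r.study_hits,
                    "n": r.study_size,
                    "K": r.term_size,
                    "N": r.universe_size,
                    "p": r.p_value,
                    "q": r.q_value,
                }
                for r in rows
            ]
        else:
            report["skipped_stages"].append("enrichment: no genic-TE genes")
    else:
        report["skipped_stages"].append("enrichment: no gene->term map")

    if inputs.gene_families is not None:
        fam_map = tio.read_gene_map(inputs.gene_families)
        fam_table = family_te_counts(assignments, fam_map)
        report["family_counts"] = {
            fam: [int(x) for x in fam_table.loc[fam]] for fam in fam_table.index
        }

    if outdir is not None:
        outdir = Path(outdir) / species_id
        outdir.mkdir(parents=True, exist_ok=True)
        counts.to_tsv(outdir / "compartment_copies.tsv", outdir / "compartment_bp.tsv")
        wf = windows_to_frame(windows)
        wf["cluster"] = clusters
        wf.to_csv(outdir / "density_windows.tsv", sep="\t", index=False)
        tio.write_bed(
            [(seg.interval, seg.label) for seg in cmap.iter_segments()],
            outdir / "compartments.bed",
        )
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def run_contrast(
    config: RunConfig,
    cultivated_id: str,
    wild_id: str,
    reports: Optional[Mapping[str, Mapping[str, Any]]] = None,
    outdir: Optional[Path | str] = None,
) -> dict[str, Any]:
    """Two-sample proportion contrast of genic and flank TE shares.

    ``reports`` may carry precomputed per-species reports (e.g. loaded from
    ``report.json``); species without one raise, matching the contract that
    both species must be analyzed first.
    """
    reports = dict(reports or {})
    for sid in (cultivated_id, wild_id):
        if sid not in reports:
            if outdir is not None and (Path(outdir) / sid / "report.json").exists():
                with open(Path(outdir) / sid / "report.json") as fh:
                    reports[sid] = json.load(fh)
            else:
                raise PipelineError(
                    "contrast", f"species {sid!r} has not been analyzed yet"
                )
    a, b = reports[cultivated_id], reports[wild_id]
    if "depletion_test" not in a or "depletion_test" not in b:
        raise PipelineError("contrast", "a species report lacks TE statistics")
    k1, n1 = a["depletion_test"]["observed_genic"], a["depletion_test"]["n_tes"]
    k2, n2 = b["depletion_test"]["observed_genic"], b["depletion_test"]["n_tes"]
    genic = prop_test_two_sample(k1, n1, k2, n2, correction=config.correction)
    contrast = {
        "cultivated": cultivated_id,
        "wild": wild_id,
        "genic": {
            "k1": k1,
            "n1": n1,
            "k2": k2,
            "n2": n2,
            "statistic": genic.statistic,
            "p_value": genic.p_value,
            "significant": genic.p_value <= config.alpha,
            "direction": (
                "cultivated_lower" if k1 / n1 < k2 / n2
                else "cultivated_higher" if k1 / n1 > k2 / n2 else "equal"
            ),
        },
        "provenance": _provenance(config),
    }
    if "flank_copies" in a and "flank_copies" in b:
        fk1, fk2 = a["flank_copies"], b["flank_copies"]
        flank = prop_test_two_sample(fk1, n1, fk2, n2, correction=config.correction)
        contrast["flank"] = {
            "k1": fk1,
            "n1": n1,
            "k2": fk2,
            "n2": n2,
            "statistic": flank.statistic,
            "p_value": flank.p_value,
            "significant": flank.p_value <= config.alpha,
        }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / f"contrast_{cultivated_id}_vs_{wild_id}.json", "w") as fh:
            json.dump(contrast, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return contrast
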