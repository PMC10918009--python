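"""End-to-end orchestration over a genome or a simulated bundle.

``run_pipeline`` drives simulate -> discover -> profile -> context ->
distribution -> date (-> regulate when a category map is given) and writes
each stage's table plus a consolidated ``summary.json`` holding the headline
statistics: length summary, complete-deletion counts, context summary,
distribution test, and age summary.  Output is deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .reference import DEFAULT_LAYOUT

_version = "0.1.0"

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All pipeline inputs and parameters, JSON round-trippable."""

    out_dir: str = "ervscape_out"
    seed: int = 0
    # inputs (None -> simulate a bundle)
    genome_fasta: str | None = None
    genes_gff3: str | None = None
    categories_gmt: str | None = None
    reference_fasta: str | None = None
    layout: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LAYOUT)
    )
    # simulation
    n_chromosomes: int = 3
    chromosome_length: int = 120_000
    n_planted: int = 6
    planted_divergence: float = 0.05
    gene_density: float = 0.15
    # discovery
    k: int = 11
    step: int = 5
    min_identity: float = 0.90
    min_len: int = 25
    merge_gap: int = 2000
    deletion_qgap_threshold: float = 0.10
    insertion_bases_threshold: int = 1000
    # structure / dating / regulation
    solo_ltr_min_cov: float = 0.5
    min_region_cov: float = 0.90
    clock_rate_pct_per_myr: float = 0.2
    great_up: int = 5000
    great_down: int = 1000
    great_max_extension: int = 1_000_000
    ltr_min_cov: float = 0.70
    ora_min_size: int = 5
    ora_max_size: int = 2000
    ora_top: int = 10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.clock_rate_pct_per_myr <= 0:
            raise ValueError("clock rate must be > 0")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = json.load(handle)
        raw["layout"] = {k: tuple(v) for k, v in raw.get("layout", {}).items()}
        return cls(**raw)


def _default_plans(config: RunConfig):
    """Evenly spaced full-to-truncated planted copies across chromosomes."""
    from .simulate import InsertionPlan

    total = config.layout["3'LTR"][1]
    kept_choices = [
        ((1, total),),                       # full-length
        ((1, total // 2),),                  # 5' half
        ((total // 3, total),),              # 3' two thirds
        ((config.layout["3'LTR"][0], total),),  # solo 3'LTR
    ]
    plans = []
    for i in range(config.n_planted):
        chrom = f"chr{i % config.n_chromosomes + 1}"
        position = 15_000 + (i // config.n_chromosomes) * 45_000
        plans.append(
            InsertionPlan(
                chrom=chrom, position=position,
                strand="+" if i % 2 == 0 else "-",
                kept_intervals=kept_choices[i % len(kept_choices)],
                divergence=config.planted_divergence,
                name=f"planted{i + 1}",
            )
        )
    return plans


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns (and writes) the summary dictionary."""
    from Bio import SeqIO

    from .context import classify_loci, read_genes_gff3, summarize_context
    from .dating import date_loci, summarize_ages, write_age_table
    from .discovery import (
        SearchParams, assemble_loci, kmer_search, write_locus_bed, write_locus_table,
    )
    from .distribution import distribution_test, nongap_length
    from .regulatory import (
        associate_ltrs, eligible_ltr_loci, ora_enrichment, read_gmt,
        regulatory_domains, write_associations, write_enrichment,
    )
    from .simulate import generate_reference, plant_loci
    from .structure import (
        count_complete_deletions, detect_solo_ltr, profile_locus,
        summarize_lengths, write_integrity_table,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    logger.info("ervscape %s seed=%d out=%s", _version, config.seed, out)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    # --- reference -----------------------------------------------------
    if config.reference_fasta:
        rec = next(SeqIO.parse(config.reference_fasta, "fasta"))
        from .reference import ProviralReference

        reference = ProviralReference(rec.id, str(rec.seq).upper(), dict(config.layout))
    else:
        reference = stage(
            "reference", generate_reference, config.layout, seed=config.seed
        )

    # --- inputs ---------------------------------------------------------
    if config.genome_fasta:
        chromosomes = {
            r.id: str(r.seq).upper() for r in SeqIO.parse(config.genome_fasta, "fasta")
        }
        genes = read_genes_gff3(config.genes_gff3) if config.genes_gff3 else []
        truth = None
    else:
        bundle = stage(
            "simulate", plant_loci, reference, _default_plans(config),
            {f"chr{i + 1}": config.chromosome_length for i in range(config.n_chromosomes)},
            seed=config.seed, out_dir=out / "bundle",
            gene_density=config.gene_density,
        )
        chromosomes = bundle.chromosomes
        genes = bundle.genes
        truth = bundle.truth

    # --- discovery ------------------------------------------------------
    params = SearchParams(
        k=config.k, step=config.step, min_identity=config.min_identity,
        min_len=config.min_len,
    )
    records = stage("discover", kmer_search, chromosomes, reference, params)
    loci = stage(
        "assemble", assemble_loci, records, reference,
        merge_gap=config.merge_gap,
        deletion_qgap_threshold=config.deletion_qgap_threshold,
        insertion_bases_threshold=config.insertion_bases_threshold,
    )
    loci = stage("context", classify_loci, loci, genes)
    write_locus_table(loci, out / "loci.tsv")
    write_locus_bed(loci, out / "loci.bed")

    # --- structure ------------------------------------------------------
    profiles = [stage("profile", profile_locus, l, reference) for l in loci]
    write_integrity_table(profiles, out / "integrity.tsv")
    summary: dict = {
        "version": _version,
        "seed": config.seed,
        "n_loci": len(loci),
        "length_summary": None,
        "deletion_counts": count_complete_deletions(profiles),
        "solo_ltr_count": sum(
            detect_solo_ltr(p, config.solo_ltr_min_cov) for p in profiles
        ),
        "context_summary": None,
        "distribution": None,
        "age_summary": None,
    }
    if loci:
        ls = stage("lengths", summarize_lengths, loci)
        summary["length_summary"] = {
            "n": ls.n, "mean_bp": ls.mean_bp, "min_bp": ls.min_bp,
            "max_bp": ls.max_bp, "coarse_counts": ls.coarse_counts,
        }
        cs = stage("context_summary", summarize_context, [l.context for l in loci])
        summary["context_summary"] = {"counts": cs.counts, "percentages": cs.percentages}

        nongap = {c: nongap_length(s) for c, s in chromosomes.items()}
        dist = stage("distribution", distribution_test, loci, nongap, alpha=config.alpha)
        summary["distribution"] = {
            "statistic": dist.statistic, "df": dist.df, "p_value": dist.p_value,
            "flags": {c: f["flag"] for c, f in dist.flags.items()},
        }

        ages = stage(
            "date", date_loci, records, chromosomes, reference,
            min_region_cov=config.min_region_cov,
            rate_pct_per_myr=config.clock_rate_pct_per_myr,
        )
        write_age_table(ages, out / "ages.tsv")
        if ages:
            summary["age_summary"] = summarize_ages(ages)

    # --- regulation (needs annotation; categories optional) -------------
    if genes and loci:
        domains = stage(
            "regulate", regulatory_domains, genes,
            up=config.great_up, down=config.great_down,
            max_extension=config.great_max_extension,
            chrom_lengths={c: len(s) for c, s in chromosomes.items()},
        )
        ltrs = eligible_ltr_loci(loci, profiles, min_ltr_cov=config.ltr_min_cov)
        associations = stage("associate", associate_ltrs, ltrs, domains, genes)
        write_associations(associations, out / "associations.tsv")
        summary["n_ltr_associations"] = len(associations)
        if config.categories_gmt:
            categories = read_gmt(config.categories_gmt)
            gene_ids = sorted({a.gene_id for a in associations})
            universe = sorted({g.gene_id for g in genes})
            enrichment = stage(
                "ora", ora_enrichment, gene_ids, categories, universe,
                min_size=config.ora_min_size, max_size=config.ora_max_size,
                top=config.ora_top,
            )
            write_enrichment(enrichment, out / "enrichment.tsv")
            summary["n_enriched_categories"] = len(enrichment)
    elif config.categories_gmt and not genes:
        raise StageError("regulate", ValueError("categories given but no gene annotation"))

    if truth is not None:
        summary["n_planted"] = len(truth)

    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    return summary
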