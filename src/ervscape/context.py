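"""Genomic-context classification of proviral loci against gene annotation.

Labels form a partition: ``intergenic`` (no gene overlap), ``intron``
(inside a gene, no exon overlap), ``exon`` (fully inside exon sequence),
``exonic&intronic`` (inside a gene, overlapping both), and
``genic&intergenic`` (spanning a gene boundary).  Classification is
strand-agnostic; where isoforms disagree, exon overlap takes precedence for
the overlapped base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gffutils

from .simulate import GeneModel

logger = logging.getLogger(__name__)

LABELS = ("intergenic", "intron", "exonic&intronic", "genic&intergenic", "exon")


def read_genes_gff3(path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features from a GFF3 file."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = tuple(
            sorted(
                (e.start, e.end)
                for e in db.children(gene, featuretype="exon")
            )
        )
        genes.append(
            GeneModel(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                start=gene.start, end=gene.end, exons=exons,
            )
        )
    return genes


def classify_context(
    chrom: str, start: int, end: int, genes: list[GeneModel],
    annotated_chroms: set[str] | None = None,
) -> str:
    """Context label for a 1-based inclusive locus interval."""
    if annotated_chroms is not None and chrom not in annotated_chroms:
        logger.warning("chromosome %s absent from annotation; calling intergenic", chrom)
        return "intergenic"
    overlapping = [
        g for g in genes
        if g.chrom == chrom and g.start <= end and g.end >= start
    ]
    if not overlapping:
        return "intergenic"
    # any locus base outside every overlapping gene -> spans a gene boundary
    gene_cover = _union([(g.start, g.end) for g in overlapping])
    if _covered_length(gene_cover, start, end) < end - start + 1:
        return "genic&intergenic"
    exon_cover = _union(
        [iv for g in overlapping for iv in g.exons]
    )
    exon_bases = _covered_length(exon_cover, start, end)
    if exon_bases == 0:
        return "intron"
    if exon_bases == end - start + 1:
        return "exon"
    return "exonic&intronic"


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _covered_length(union: list[tuple[int, int]], start: int, end: int) -> int:
    return sum(max(0, min(e, end) - max(s, start) + 1) for s, e in union)


@dataclass(frozen=True)
class ContextSummary:
    counts: dict[str, int]
    percentages: dict[str, float]

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def normalize_label(label: str) -> str:
    return label.replace(" ", "")


def summarize_context(labels: list[str]) -> ContextSummary:
    """Counts and 2-decimal percentages per context label."""
    from .util import round_half_up

    if not labels:
        raise ValueError("summarize_context requires at least one label")
    counts: dict[str, int] = {}
    for label in labels:
        key = normalize_label(label)
        counts[key] = counts.get(key, 0) + 1
    n = len(labels)
    percentages = {k: round_half_up(100.0 * v / n, 2) for k, v in counts.items()}
    return ContextSummary(counts=counts, percentages=percentages)


def classify_loci(loci, genes: list[GeneModel]):
    """Attach context labels to loci; returns new ProviralLocus objects."""
    from dataclasses import replace

    annotated = {g.chrom for g in genes}
    return [
        replace(
            l,
            context=classify_context(l.chrom, l.start, l.end, genes, annotated),
        )
        for l in loci
    ]
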