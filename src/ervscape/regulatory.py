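"""Cis-regulatory association of LTR loci with genes, and enrichment.

Gene regulatory domains follow the GREAT basal+extension rule: a strand-
aware basal window around the TSS (default 5 kb upstream / 1 kb downstream)
extended on each side up to a maximum (default 1 Mb), stopping at the
nearest other gene's basal domain and at chromosome ends.  Basal domains are
inviolate: when two basal domains overlap, extension in that direction is
zero.  An LTR locus is associated with every gene whose extended domain it
overlaps; the reported distance is from the LTR interval midpoint to the
TSS, binned into <5 kb, 5-50 kb, 50-500 kb and >500 kb.

Over-representation analysis tests an associated-gene list against gene
categories with the hypergeometric upper tail and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import GeneModel

DISTANCE_BINS = ("<5kb", "5-50kb", "50-500kb", ">500kb")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    basal: tuple[int, int]      # 1-based inclusive
    extended: tuple[int, int]

    def __post_init__(self) -> None:
        bs, be = self.basal
        es, ee = self.extended
        if not (es <= bs <= be <= ee):
            raise ValueError(
                f"basal {self.basal} not contained in extended {self.extended}"
            )


def basal_domain(gene: GeneModel, up: int, down: int, chrom_len: int) -> tuple[int, int]:
    if gene.strand == "+":
        lo, hi = gene.tss - up, gene.tss + down
    else:
        lo, hi = gene.tss - down, gene.tss + up
    return max(1, lo), min(chrom_len, hi)


def regulatory_domains(
    genes: list[GeneModel],
    up: int = 5000,
    down: int = 1000,
    max_extension: int = 1_000_000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Basal+extension regulatory domains for a gene set."""
    if chrom_lengths is None:
        raise ValueError("chrom_lengths is required to clip domains")
    for gene in genes:
        if gene.chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {gene.chrom!r} for gene {gene.gene_id}")
        if not 1 <= gene.tss <= chrom_lengths[gene.chrom]:
            raise ValueError(f"TSS of {gene.gene_id} outside chromosome")
    basals = {
        g.gene_id: basal_domain(g, up, down, chrom_lengths[g.chrom]) for g in genes
    }
    domains: list[RegulatoryDomain] = []
    for gene in genes:
        bs, be = basals[gene.gene_id]
        chrom_len = chrom_lengths[gene.chrom]
        left = max(1, bs - max_extension)
        right = min(chrom_len, be + max_extension)
        for other in genes:
            if other.gene_id == gene.gene_id or other.chrom != gene.chrom:
                continue
            obs, obe = basals[other.gene_id]
            if obe < bs:               # neighbor entirely to the left
                left = max(left, obe)
            elif obs > be:             # neighbor entirely to the right
                right = min(right, obs)
            else:                      # overlapping basal domains: no extension
                if obs < bs:
                    left = bs
                if obe > be:
                    right = be
        domains.append(
            RegulatoryDomain(
                gene_id=gene.gene_id, chrom=gene.chrom,
                basal=(bs, be),
                extended=(min(left, bs), max(right, be)),
            )
        )
    return domains


@dataclass(frozen=True)
class Association:
    locus: str
    gene_id: str
    signed_distance: int   # LTR midpoint -> TSS, upstream negative (gene frame)
    distance_bin: str
    orientation: str       # upstream / downstream of the TSS


def _bin_distance(abs_distance: int) -> str:
    if abs_distance < 5_000:
        return "<5kb"
    if abs_distance <= 50_000:
        return "5-50kb"
    if abs_distance <= 500_000:
        return "50-500kb"
    return ">500kb"


def associate_ltrs(
    ltr_loci,
    domains: list[RegulatoryDomain],
    genes: list[GeneModel],
) -> list[Association]:
    """One association per (LTR locus, gene) with overlapping extended domain."""
    by_id = {g.gene_id: g for g in genes}
    out: list[Association] = []
    for locus in ltr_loci:
        midpoint = (locus.start + locus.end) // 2
        for dom in domains:
            if dom.chrom != locus.chrom:
                continue
            es, ee = dom.extended
            if locus.start <= ee and locus.end >= es:
                gene = by_id[dom.gene_id]
                raw = midpoint - gene.tss
                signed = raw if gene.strand == "+" else -raw
                out.append(
                    Association(
                        locus=locus.name, gene_id=gene.gene_id,
                        signed_distance=signed,
                        distance_bin=_bin_distance(abs(signed)),
                        orientation="upstream" if signed < 0 else "downstream",
                    )
                )
    return out


def eligible_ltr_loci(loci, profiles, min_ltr_cov: float = 0.70):
    """Loci whose better-retained LTR exceeds the coverage floor."""
    by_name = {p.locus: p for p in profiles}
    out = []
    for locus in loci:
        profile = by_name.get(locus.name)
        if profile is None:
            continue
        if max(profile["5'LTR"], profile["3'LTR"]) > min_ltr_cov:
            out.append(locus)
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    category_size: int
    overlap: int
    enrichment_ratio: float
    p_value: float
    fdr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError("FDR outside [0,1]")


def ora_enrichment(
    gene_list,
    categories: dict[str, set[str]],
    universe,
    min_size: int = 5,
    max_size: int = 2000,
    top: int = 10,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation with BH FDR, top categories only."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_list)
    if not gene_set <= universe:
        raise ValueError(f"gene list not contained in universe: {gene_set - universe}")
    n_universe = len(universe)
    n_list = len(gene_set)
    tested: list[tuple[str, int, int, float, float]] = []
    for cat, members in sorted(categories.items()):
        members = set(members) & universe
        k_cat = len(members)
        if not min_size <= k_cat <= max_size:
            continue
        overlap = len(members & gene_set)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, k_cat, n_list))
        expected = k_cat * n_list / n_universe
        ratio = overlap / expected if expected > 0 else 0.0
        tested.append((cat, k_cat, overlap, ratio, p))
    if not tested:
        return []
    _, fdrs, _, _ = multipletests([t[4] for t in tested], method="fdr_bh")
    results = [
        EnrichmentResult(
            category=cat, category_size=k_cat, overlap=overlap,
            enrichment_ratio=ratio, p_value=p, fdr=float(q),
        )
        for (cat, k_cat, overlap, ratio, p), q in zip(tested, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.p_value, r.category))
    return results[:top]


def read_gmt(path) -> dict[str, set[str]]:
    """GMT category map: name, description, member genes (tab-separated)."""
    categories: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                categories[fields[0]] = set(fields[2:])
    return categories


def write_associations(associations: list[Association], path) -> None:
    with open(path, "w") as handle:
        handle.write("locus\tgene\tsigned_distance\tbin\torientation\n")
        for a in associations:
            handle.write(
                f"{a.locus}\t{a.gene_id}\t{a.signed_distance}\t"
                f"{a.distance_bin}\t{a.orientation}\n"
            )


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    with open(path, "w") as handle:
        handle.write("category\tsize\toverlap\tenrichment_ratio\tp\tfdr\n")
        for r in results:
            handle.write(
                f"{r.category}\t{r.category_size}\t{r.overlap}\t"
                f"{r.enrichment_ratio:.4g}\t{r.p_value:.4g}\t{r.fdr:.4g}\n"
            )
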