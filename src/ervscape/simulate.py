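"""Synthetic genomes with planted proviral insertions.

Generates (i) a random proviral consensus for a given region layout, (ii)
multi-chromosome background genomes, (iii) planted proviral copies with
controlled truncation, point-mutation divergence, strand, and nested foreign
insertions, and (iv) simple multi-exon gene models so genomic-context labels
have a defined truth.  Every output is reproducible for a fixed seed, and a
machine-readable truth table records the realized coordinates of each copy.

The mutation model is substitutions only (uniform across sites, replacement
uniform over the three alternative bases), so the realized divergence of a
planted copy is directly the p-distance that molecular-clock dating is
expected to recover.  Truncations and nested insertions are modeled
explicitly through :class:`InsertionPlan` rather than through an indel
process.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import DEFAULT_LAYOUT, ProviralReference, validate_layout

_BASES = "ACGT"
_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

CONTEXT_LABELS = ("intergenic", "intron", "exon", "exonic&intronic", "genic&intergenic")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])


def generate_reference(
    layout: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
    name: str = "HML-8_consensus",
) -> ProviralReference:
    """Random A/C/G/T consensus of the layout's total length (deterministic)."""
    layout = dict(DEFAULT_LAYOUT) if layout is None else dict(layout)
    total = validate_layout(layout)
    rng = np.random.default_rng([seed, 101])  # salted: independent stream per role
    seq = list(_random_sequence(rng, total))
    # a provirus carries the same LTR at both ends; mirror them so LTR-LTR
    # divergence dating behaves as it does for real elements
    (s5, e5), (s3, e3) = layout["5'LTR"], layout["3'LTR"]
    if e5 - s5 == e3 - s3:
        seq[s3 - 1 : e3] = seq[s5 - 1 : e5]
    return ProviralReference(name=name, sequence="".join(seq), layout=layout)


def mutate_sequence(seq: str, divergence: float, seed: int = 0) -> str:
    """Substitute each site independently with probability ``divergence``.

    Replacement bases are uniform over the three alternatives; non-ACGT
    characters are left untouched.  Length is preserved.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError(f"divergence must be in [0, 0.5], got {divergence}")
    if divergence == 0.0 or not seq:
        return seq
    rng = np.random.default_rng([seed, 202])
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    idx = lut[arr]
    hit = (rng.random(arr.size) < divergence) & (idx >= 0)
    shift = rng.integers(1, 4, size=arr.size)
    new_idx = (idx + shift) % 4
    encode = np.frombuffer(_BASES.encode("ascii"), dtype=np.uint8)
    arr[hit] = encode[new_idx[hit]]
    return arr.tobytes().decode("ascii")


@dataclass(frozen=True)
class InsertionPlan:
    """One planted proviral copy: where, what is kept, and how diverged.

    ``kept_intervals`` are 1-based inclusive on the reference, disjoint and
    ascending.  ``nested_inserts`` are (reference offset, foreign length)
    pairs: a random foreign segment is spliced in immediately after the kept
    base at that reference coordinate.  ``context`` is the genomic context
    the simulator will realize around the copy via gene models.
    """

    chrom: str
    position: int
    strand: str = "+"
    kept_intervals: tuple[tuple[int, int], ...] = ((1, 10485),)
    divergence: float = 0.0
    nested_inserts: tuple[tuple[int, int], ...] = ()
    context: str = "intergenic"
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError(f"divergence must be in [0, 0.5], got {self.divergence}")
        prev_end = 0
        for start, end in self.kept_intervals:
            if start <= prev_end or end < start:
                raise ValueError(
                    f"kept intervals must be disjoint and ascending: {self.kept_intervals}"
                )
            prev_end = end
        if self.context not in CONTEXT_LABELS:
            raise ValueError(f"unknown context {self.context!r}")

    @property
    def kept_length(self) -> int:
        return sum(e - s + 1 for s, e in self.kept_intervals)


@dataclass(frozen=True)
class GeneModel:
    """A gene with exons; TSS is the gene start on +, the gene end on -."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for s, e in self.exons:
            if s < self.start or e > self.end or e < s:
                raise ValueError(f"exon [{s},{e}] outside gene {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class GenomeBundle:
    """Paths plus in-memory copies of one simulated genome."""

    genome_fasta: Path
    genes_gff3: Path
    truth_tsv: Path
    chromosomes: dict[str, str]
    genes: list[GeneModel]
    truth: list[dict]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}


def _realize_insert(
    reference: ProviralReference, plan: InsertionPlan, rng: np.random.Generator
) -> str:
    kept = "".join(
        reference.sequence[s - 1 : e] for s, e in plan.kept_intervals
    )
    mutated = mutate_sequence(kept, plan.divergence, seed=int(rng.integers(0, 2**31)))
    # map reference offsets of nested inserts into concatenated coordinates
    pieces: list[str] = []
    cursor = 0
    for ref_offset, foreign_len in sorted(plan.nested_inserts):
        concat = 0
        found = False
        for s, e in plan.kept_intervals:
            if s <= ref_offset <= e:
                concat += ref_offset - s + 1
                found = True
                break
            concat += e - s + 1
        if not found:
            raise ValueError(
                f"nested insert offset {ref_offset} not inside kept intervals of {plan}"
            )
        pieces.append(mutated[cursor:concat])
        pieces.append(_random_sequence(rng, foreign_len))
        cursor = concat
    pieces.append(mutated[cursor:])
    realized = "".join(pieces)
    return revcomp(realized) if plan.strand == "-" else realized


def _genes_for_context(
    plan_name: str, context: str, chrom: str, start: int, end: int, chrom_len: int,
    rng: np.random.Generator,
) -> list[GeneModel]:
    """Construct gene models realizing the requested context for one locus."""
    if context == "intergenic":
        return []
    strand = "+" if rng.random() < 0.5 else "-"
    gid = f"gene_{plan_name}"
    pad = 2000
    gs, ge = max(1, start - pad), min(chrom_len, end + pad)
    if context == "intron":
        exons = ((gs, max(gs, start - pad // 2)), (min(ge, end + pad // 2), ge))
    elif context == "exon":
        exons = ((gs, ge),)
    elif context == "exonic&intronic":
        mid = (start + end) // 2
        exons = ((gs, mid), (min(ge, end + pad // 2), ge))
    elif context == "genic&intergenic":
        mid = (start + end) // 2
        ge = mid  # gene ends inside the locus; the rest is intergenic
        exons = ((gs, gs + 200), (ge - 200, ge))
    else:  # pragma: no cover - guarded by InsertionPlan validation
        raise ValueError(context)
    exons = tuple((max(gs, s), min(ge, e)) for s, e in exons if s <= e)
    return [GeneModel(gid, chrom, strand, gs, ge, exons)]


def _background_genes(
    chrom: str, chrom_len: int, occupied: list[tuple[int, int]],
    density: float, rng: np.random.Generator,
) -> list[GeneModel]:
    """Random multi-exon genes in regions clear of planted loci."""
    genes: list[GeneModel] = []
    target = int(density * chrom_len)
    covered = 0
    taken = sorted(occupied)
    attempts = 0
    while covered < target and attempts < 200:
        attempts += 1
        length = int(rng.integers(4000, 20000))
        if chrom_len <= length + 2:
            break
        start = int(rng.integers(1, chrom_len - length))
        end = start + length - 1
        clear = all(end < s - 3000 or start > e + 3000 for s, e in taken)
        if not clear:
            continue
        n_exons = int(rng.integers(2, 6))
        bounds = np.sort(rng.choice(np.arange(start, end), size=2 * n_exons, replace=False))
        exons = tuple(
            (int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"bg_{chrom}_{len(genes)}", chrom, strand, start, end, exons))
        taken.append((start, end))
        covered += length
    return genes


def write_genes_gff3(genes: list[GeneModel], path) -> None:
    """Write gene/mRNA/exon features as GFF3."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.chrom}\tervscape_sim\t"
            handle.write(
                f"{base}gene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            handle.write(
                f"{base}mRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                handle.write(
                    f"{base}exon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}.t1\n"
                )


TRUTH_COLUMNS = [
    "name", "chrom", "start", "end", "start0", "end0", "strand",
    "kept_intervals", "divergence", "nested_inserts", "context",
]


def plant_loci(
    reference: ProviralReference,
    plans: list[InsertionPlan],
    chrom_lengths: dict[str, int],
    seed: int = 0,
    out_dir: str | Path = ".",
    gene_density: float = 0.15,
) -> GenomeBundle:
    """Build a genome bundle: FASTA + GFF3 + truth table with planted copies.

    Truth coordinates are recorded both 1-based inclusive (``start``/``end``)
    and 0-based half-open (``start0``/``end0``).
    """
    rng = np.random.default_rng([seed, 303])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    by_chrom: dict[str, list[InsertionPlan]] = {}
    for plan in plans:
        if plan.chrom not in chrom_lengths:
            raise ValueError(f"plan chromosome {plan.chrom!r} not in chrom_lengths")
        if not 1 <= plan.position <= chrom_lengths[plan.chrom]:
            raise ValueError(f"plan position {plan.position} outside {plan.chrom}")
        by_chrom.setdefault(plan.chrom, []).append(plan)
    for chrom, chrom_plans in by_chrom.items():
        seen: dict[int, InsertionPlan] = {}
        for plan in chrom_plans:
            if plan.position in seen:
                raise ValueError(
                    f"overlapping plans on {chrom} at {plan.position}: "
                    f"{seen[plan.position]} and {plan}"
                )
            seen[plan.position] = plan

    chromosomes: dict[str, str] = {}
    truth: list[dict] = []
    genes: list[GeneModel] = []
    for chrom in chrom_lengths:
        background = _random_sequence(rng, chrom_lengths[chrom])
        chrom_plans = sorted(by_chrom.get(chrom, []), key=lambda p: p.position)
        pieces: list[str] = []
        cursor = 0  # 0-based position in background consumed so far
        offset = 0  # cumulative inserted length
        realized: list[tuple[InsertionPlan, int, int]] = []
        for plan in chrom_plans:
            insert = _realize_insert(reference, plan, rng)
            pieces.append(background[cursor : plan.position - 1])
            start1 = plan.position + offset  # 1-based start of the insert
            pieces.append(insert)
            realized.append((plan, start1, start1 + len(insert) - 1))
            cursor = plan.position - 1
            offset += len(insert)
        pieces.append(background[cursor:])
        chromosomes[chrom] = "".join(pieces)

        occupied = [(s, e) for _, s, e in realized]
        for i, (plan, start1, end1) in enumerate(realized):
            name = plan.name or f"{chrom}_locus{i + 1}"
            genes.extend(
                _genes_for_context(
                    name, plan.context, chrom, start1, end1,
                    len(chromosomes[chrom]), rng,
                )
            )
            truth.append(
                {
                    "name": name,
                    "chrom": chrom,
                    "start": start1,
                    "end": end1,
                    "start0": start1 - 1,
                    "end0": end1,
                    "strand": plan.strand,
                    "kept_intervals": ";".join(f"{s}-{e}" for s, e in plan.kept_intervals),
                    "divergence": plan.divergence,
                    "nested_inserts": ";".join(
                        f"{o}+{l}" for o, l in plan.nested_inserts
                    ),
                    "context": plan.context,
                }
            )
        if gene_density > 0:
            gene_occupied = occupied + [(g.start, g.end) for g in genes if g.chrom == chrom]
            genes.extend(
                _background_genes(chrom, len(chromosomes[chrom]), gene_occupied,
                                  gene_density, rng)
            )

    genome_fasta = out_dir / "genome.fa"
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in chromosomes.items()],
        str(genome_fasta), "fasta",
    )
    genes_gff3 = out_dir / "genes.gff3"
    write_genes_gff3(genes, genes_gff3)
    truth_tsv = out_dir / "truth.tsv"
    with open(truth_tsv, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=TRUTH_COLUMNS, delimiter="\t")
        writer.writeheader()
        writer.writerows(truth)
    return GenomeBundle(genome_fasta, genes_gff3, truth_tsv, chromosomes, genes, truth)
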