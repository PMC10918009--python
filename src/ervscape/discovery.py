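"""Proviral locus discovery: BLAT-like k-mer search and locus assembly.

The search mirrors the classic DNA BLAT strategy at desk scale: the genome is
indexed with overlapping k-mers (k=11) sampled every ``step`` (5) bases;
query k-mers hitting the index seed diagonals; seeds close in diagonal and
target position are chained into candidate windows; each window is aligned
with a banded edit-distance alignment (edlib) and the alignment path is
trimmed to its well-supported core.  Hits below the identity or length floor
are discarded.  Both query strands are searched.

Assembly merges collinear alignment records on the same chromosome and
strand into named loci carrying the per-locus summary columns used for
provirus catalogs: coverage fraction of the consensus, query-gap fraction,
a 10%-wide coverage range bin, and Insertion/Deletion flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib
from Bio import SeqIO

from .psl import AlignmentRecord
from .reference import ProviralReference
from .simulate import revcomp

MAX_SEED_K = 32


@dataclass(frozen=True)
class SearchParams:
    k: int = 11
    step: int = 5
    min_identity: float = 0.95
    min_len: int = 25
    min_seeds: int = 2
    diagonal_band: int = 150  # diagonal tolerance when banding seeds
    chain_gap: int = 5000     # max target-position gap within one chain
    max_kmer_occurrence: int = 64
    pad: int = 200            # window padding before banded alignment

    def __post_init__(self) -> None:
        if self.k <= 0 or self.step <= 0 or self.min_len <= 0:
            raise ValueError("k, step and min_len must be positive")
        if self.k > MAX_SEED_K:
            raise ValueError(f"k={self.k} exceeds seed width limit {MAX_SEED_K}")


@dataclass(frozen=True)
class ProviralLocus:
    """A named genomic provirus locus with catalog summary columns."""

    chrom: str
    strand: str
    start: int   # 1-based inclusive
    end: int
    coverage_fraction: float
    q_gap_fraction: float
    match: int
    mismatch: int
    q_gap_bases: int
    insertion_bases: int
    indel_flags: frozenset[str] = frozenset()
    context: str | None = None
    covered_ref_intervals: tuple[tuple[int, int], ...] = ()
    # covered_ref_intervals: 1-based inclusive consensus intervals

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"locus end {self.end} < start {self.start}")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError(f"coverage_fraction {self.coverage_fraction} outside [0,1]")
        if not 0.0 <= self.q_gap_fraction < 1.0:
            raise ValueError(f"q_gap_fraction {self.q_gap_fraction} outside [0,1)")

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def range_bin(self) -> str:
        lo = min(int(self.coverage_fraction * 100) // 10 * 10, 90)
        return f"[{lo}%-{lo + 10}%)"


def _load_genome(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return genome
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")}


def _index_genome(chromosomes: dict[str, str], k: int, step: int, max_occ: int):
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in chromosomes.items():
        for i in range(0, len(seq) - k + 1, step):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((chrom, i))
    # simple occurrence cap against repeat-saturated words
    return {kmer: hits for kmer, hits in index.items() if len(hits) <= max_occ}


def _chain_seeds(seeds: list[tuple[int, int]], diagonal_band: int, chain_gap: int):
    """Group (q, t) seeds into chains: by diagonal band, then target gaps.

    A copy differing from the consensus only by substitutions keeps a
    constant diagonal t - q, so banding on the diagonal first is robust;
    each band then splits wherever consecutive seeds are farther apart on
    the target than ``chain_gap``.
    """
    bands: list[list[tuple[int, int]]] = []
    for q, t in sorted(seeds, key=lambda s: (s[1] - s[0], s[1])):
        if bands and (t - q) - (bands[-1][-1][1] - bands[-1][-1][0]) <= diagonal_band:
            bands[-1].append((q, t))
        else:
            bands.append([(q, t)])
    chains: list[list[tuple[int, int]]] = []
    for band in bands:
        band.sort(key=lambda s: s[1])
        current: list[tuple[int, int]] = []
        for q, t in band:
            if current and t - current[-1][1] > chain_gap:
                chains.append(current)
                current = []
            current.append((q, t))
        if current:
            chains.append(current)
    return chains


def _cigar_runs(cigar: str) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            runs.append((ch, int(num)))
            num = ""
    return runs


def _trim_runs(runs: list[tuple[str, int]]):
    """Keep the maximal-scoring contiguous segment of the alignment path.

    Scores: match +1, mismatch -2; a gap run's penalty is capped at -40 so
    interior kb-scale insertions stay inside the kept segment while noisy
    flanks (random sequence at ~25% identity, or query sequence absent from
    the locus that the infix alignment was forced to consume) score steeply
    negative and fall away.  Kadane's algorithm over cigar runs.
    """
    def run_score(op: str, ln: int) -> float:
        if op == "=":
            return float(ln)
        if op == "X":
            return -2.0 * ln
        return -min(2.0 * ln, 40.0)

    scores = [run_score(op, ln) for op, ln in runs]
    best = 0.0
    best_range = (0, 0)
    running = 0.0
    seg_start = 0
    for i, s in enumerate(scores):
        if running <= 0:
            running, seg_start = s, i
        else:
            running += s
        if running > best:
            best, best_range = running, (seg_start, i + 1)
    cut_left, cut_right = best_range
    trimmed = runs[cut_left:cut_right]
    q_skip = sum(ln for op, ln in runs[:cut_left] if op in "=XI")
    t_skip = sum(ln for op, ln in runs[:cut_left] if op in "=XD")
    # drop terminal indels
    while trimmed and trimmed[0][0] in "ID":
        op, ln = trimmed.pop(0)
        q_skip += ln if op == "I" else 0
        t_skip += ln if op == "D" else 0
    while trimmed and trimmed[-1][0] in "ID":
        trimmed.pop()
    return trimmed, q_skip, t_skip


def _affine_score(runs: list[tuple[str, int]]) -> float:
    """Affine-style path score: match +1, mismatch -2, gaps open 5 + 0.5/bp
    (capped).  Unit-cost edit paths scatter spurious 1-bp indel pairs
    through diverged-but-ungapped sequence; scoring with a gap-open cost
    lets a gapless interpretation win whenever it explains the window."""
    score = 0.0
    for op, ln in runs:
        if op == "=":
            score += ln
        elif op == "X":
            score -= 2.0 * ln
        else:
            score -= 5.0 + min(0.5 * ln, 40.0)
    return score


def _gapless_runs(
    qseq_window: str, tseq: str, offset: int
) -> tuple[list[tuple[str, int]], int, int] | None:
    """Ungapped comparison of the window along a fixed diagonal.

    ``offset`` is the target position aligned to query window position 0.
    Returns (runs, q_off, t_off) after trimming, like the edlib path.
    """
    q_lo = max(0, -offset)
    q_hi = min(len(qseq_window), len(tseq) - offset)
    if q_hi - q_lo < 1:
        return None
    runs: list[tuple[str, int]] = []
    for i in range(q_lo, q_hi):
        op = "=" if qseq_window[i] == tseq[i + offset] else "X"
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
    trimmed, q_skip, t_skip = _trim_runs(runs)
    if not trimmed:
        return None
    return trimmed, q_lo + q_skip, q_lo + offset + t_skip


def _record_from_alignment(
    qseq_window: str, tseq: str, qa: int, ta: int, strand: str,
    q_name: str, t_name: str, q_size: int, t_size: int,
    diagonal: int | None = None,
) -> AlignmentRecord | None:
    """Align a candidate window and convert the path to an AlignmentRecord.

    ``qa``/``ta`` are the window offsets in strand-oriented query / target
    coordinates.  When the seed ``diagonal`` (t - q) is given, a gapless
    interpretation along it competes with the edit-distance path and the
    higher-scoring one wins.  Minus-strand query coordinates are converted
    to the plus-strand consensus convention.
    """
    candidates: list[tuple[list[tuple[str, int]], int, int]] = []
    result = edlib.align(qseq_window, tseq, mode="HW", task="path")
    if result["editDistance"] >= 0 and result.get("cigar"):
        t_loc = result["locations"][0][0]
        runs, q_off, t_off = _trim_runs(_cigar_runs(result["cigar"]))
        if runs:
            candidates.append((runs, q_off, t_loc + t_off))
    if diagonal is not None:
        gapless = _gapless_runs(qseq_window, tseq, diagonal - (ta - qa))
        if gapless is not None:
            candidates.append(gapless)
    if not candidates:
        return None
    runs, q_off, t_off = max(candidates, key=lambda c: _affine_score(c[0]))
    q = qa + q_off
    t = ta + t_off
    blocks: list[tuple[int, int, int]] = []
    match = mismatch = 0
    q_gap_count = q_gap_bases = t_gap_count = t_gap_bases = 0
    cur: tuple[int, int, int] | None = None  # (q_start, t_start, len) strand coords
    for op, ln in runs:
        if op in "=X":
            if op == "=":
                match += ln
            else:
                mismatch += ln
            if cur is not None and cur[0] + cur[2] == q and cur[1] + cur[2] == t:
                cur = (cur[0], cur[1], cur[2] + ln)
            else:
                if cur is not None:
                    blocks.append(cur)
                cur = (q, t, ln)
            q += ln
            t += ln
        elif op == "I":  # query base absent from target: consensus deletion
            q_gap_count += 1
            q_gap_bases += ln
            q += ln
        elif op == "D":  # extra target bases: insertion into the provirus
            t_gap_count += 1
            t_gap_bases += ln
            t += ln
    if cur is not None:
        blocks.append(cur)
    if not blocks:
        return None
    if strand == "-":
        blocks = [(q_size - (bq + ln), bt, ln) for bq, bt, ln in blocks]
    q_lo = min(bq for bq, _, ln in blocks)
    q_hi = max(bq + ln for bq, _, ln in blocks)
    return AlignmentRecord(
        q_name=q_name, t_name=t_name, strand=strand,
        match=match, mismatch=mismatch,
        q_gap_count=q_gap_count, q_gap_bases=q_gap_bases,
        t_gap_count=t_gap_count, t_gap_bases=t_gap_bases,
        q_size=q_size, q_start=q_lo, q_end=q_hi,
        t_size=t_size, t_start=blocks[0][1], t_end=blocks[-1][1] + blocks[-1][2],
        blocks=tuple(blocks),
    )


def kmer_search(
    genome,
    reference: ProviralReference,
    params: SearchParams | None = None,
) -> list[AlignmentRecord]:
    """Find local alignments of the consensus in a genome (both strands)."""
    params = params or SearchParams()
    chromosomes = _load_genome(genome)
    if not chromosomes or all(len(s) < params.k for s in chromosomes.values()):
        return []
    index = _index_genome(
        chromosomes, params.k, params.step, params.max_kmer_occurrence
    )
    q_size = len(reference)
    records: list[AlignmentRecord] = []
    for strand in "+-":
        qseq = reference.sequence if strand == "+" else revcomp(reference.sequence)
        seeds_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for qpos in range(0, len(qseq) - params.k + 1):
            hits = index.get(qseq[qpos : qpos + params.k])
            if hits:
                for chrom, tpos in hits:
                    seeds_by_chrom.setdefault(chrom, []).append((qpos, tpos))
        for chrom, seeds in seeds_by_chrom.items():
            tseq = chromosomes[chrom]
            for chain in _chain_seeds(seeds, params.diagonal_band, params.chain_gap):
                if len(chain) < params.min_seeds:
                    continue
                q_lo = min(q for q, _ in chain)
                q_hi = max(q for q, _ in chain) + params.k
                t_lo = min(t for _, t in chain)
                t_hi = max(t for _, t in chain) + params.k
                qa = max(0, q_lo - params.pad)
                qb = min(len(qseq), q_hi + params.pad)
                ta = max(0, t_lo - 2 * params.pad)
                tb = min(len(tseq), t_hi + 2 * params.pad)
                diagonals = sorted(t - q for q, t in chain)
                rec = _record_from_alignment(
                    qseq[qa:qb], tseq[ta:tb], qa, ta, strand,
                    reference.name, chrom, q_size, len(tseq),
                    diagonal=diagonals[len(diagonals) // 2],
                )
                if rec is None or rec.aligned_bases < params.min_len:
                    continue
                if rec.match / rec.aligned_bases < params.min_identity:
                    continue
                records.append(rec)
    return _dedup_records(records)


def _dedup_records(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Drop records mostly contained in a better record on the same target."""
    kept: list[AlignmentRecord] = []
    for rec in sorted(records, key=lambda r: -r.aligned_bases):
        redundant = False
        for other in kept:
            if other.t_name != rec.t_name:
                continue
            overlap = min(other.t_end, rec.t_end) - max(other.t_start, rec.t_start)
            if overlap > 0.5 * (rec.t_end - rec.t_start):
                redundant = True
                break
        if not redundant:
            kept.append(rec)
    return sorted(kept, key=lambda r: (r.t_name, r.t_start))


def assemble_loci(
    records: list[AlignmentRecord],
    reference: ProviralReference,
    merge_gap: int = 2000,
    deletion_qgap_threshold: float = 0.10,
    insertion_bases_threshold: int = 1000,
    collinear_tolerance: int = 100,
) -> list[ProviralLocus]:
    """Merge collinear records into named loci with catalog columns.

    Records on one chromosome and strand whose genomic intervals are within
    ``merge_gap`` and whose consensus intervals are collinear become one
    locus.  ``coverage_fraction`` is total aligned bases over the consensus
    length; the query-gap fraction is Qgap/(match+mismatch+Qgap); a
    Deletion flag is raised when that fraction reaches the threshold, an
    Insertion flag when the genomic length exceeds the aligned consensus
    span by at least ``insertion_bases_threshold``.
    """
    if not records:
        return []
    q_names = {r.q_name for r in records}
    if len(q_names) > 1:
        raise ValueError(f"records from multiple references mixed: {sorted(q_names)}")

    groups: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for rec in records:
        groups.setdefault((rec.t_name, rec.strand), []).append(rec)

    loci: list[ProviralLocus] = []
    ref_len = len(reference)
    for (chrom, strand), recs in groups.items():
        recs.sort(key=lambda r: r.t_start)
        clusters: list[list[AlignmentRecord]] = []
        for rec in recs:
            if clusters and rec.t_start - clusters[-1][-1].t_end <= merge_gap and \
                    _collinear(clusters[-1][-1], rec, collinear_tolerance):
                clusters[-1].append(rec)
            else:
                clusters.append([rec])
        for cluster in clusters:
            match = sum(r.match for r in cluster)
            mismatch = sum(r.mismatch for r in cluster)
            q_gap = sum(r.q_gap_bases for r in cluster)
            # consensus bases skipped between merged records also count as Qgap
            ivs: list[tuple[int, int]] = []
            for r in cluster:
                ivs.extend(r.query_intervals())
            ivs.sort()
            merged_ivs: list[tuple[int, int]] = []
            for s, e in ivs:
                if merged_ivs and s <= merged_ivs[-1][1]:
                    merged_ivs[-1] = (merged_ivs[-1][0], max(merged_ivs[-1][1], e))
                else:
                    merged_ivs.append((s, e))
            for (_, e0), (s1, _) in zip(merged_ivs, merged_ivs[1:]):
                q_gap += s1 - e0
            start = min(r.t_start for r in cluster) + 1
            end = max(r.t_end for r in cluster)
            length = end - start + 1
            insertion_bases = max(0, length - (match + mismatch))
            flags = set()
            aligned = match + mismatch
            q_gap_fraction = q_gap / (aligned + q_gap) if aligned + q_gap else 0.0
            if q_gap_fraction >= deletion_qgap_threshold:
                flags.add("Deletion")
            if insertion_bases >= insertion_bases_threshold:
                flags.add("Insertion")
            loci.append(
                ProviralLocus(
                    chrom=chrom, strand=strand, start=start, end=end,
                    coverage_fraction=min(1.0, aligned / ref_len),
                    q_gap_fraction=q_gap_fraction,
                    match=match, mismatch=mismatch, q_gap_bases=q_gap,
                    insertion_bases=insertion_bases,
                    indel_flags=frozenset(flags),
                    covered_ref_intervals=tuple(
                        (s + 1, e) for s, e in merged_ivs
                    ),
                )
            )
    loci.sort(key=lambda l: (-l.coverage_fraction, l.chrom, l.start))
    return loci


def _collinear(prev: AlignmentRecord, nxt: AlignmentRecord, tol: int) -> bool:
    if prev.strand == "+":
        return nxt.q_start >= prev.q_end - tol
    return nxt.q_end <= prev.q_start + tol


def discover_loci(
    genome,
    reference: ProviralReference,
    params: SearchParams | None = None,
    merge_gap: int = 2000,
    **assemble_kwargs,
) -> list[ProviralLocus]:
    """Convenience: k-mer search then locus assembly."""
    records = kmer_search(genome, reference, params)
    return assemble_loci(records, reference, merge_gap=merge_gap, **assemble_kwargs)


LOCUS_TABLE_COLUMNS = [
    "name", "chrom", "strand", "start", "end", "length",
    "coverage_pct", "range_bin", "qgap_pct", "indel", "context",
]


def write_locus_table(loci: list[ProviralLocus], path: str | Path) -> None:
    """Write a catalog-style TSV (1-based inclusive coordinates)."""
    with open(path, "w") as handle:
        handle.write("\t".join(LOCUS_TABLE_COLUMNS) + "\n")
        for l in loci:
            indel = ",".join(
                f for f in ("Insertion", "Deletion") if f in l.indel_flags
            ) or "NA"
            handle.write(
                "\t".join(
                    [
                        l.name, l.chrom, l.strand, str(l.start), str(l.end),
                        str(l.length), f"{l.coverage_fraction * 100:.2f}%",
                        l.range_bin, f"{l.q_gap_fraction * 100:.2f}%",
                        indel, l.context or "NA",
                    ]
                )
                + "\n"
            )


def write_locus_bed(loci: list[ProviralLocus], path: str | Path) -> None:
    """Write loci as BED6 (0-based half-open)."""
    with open(path, "w") as handle:
        for l in sorted(loci, key=lambda x: (x.chrom, x.start)):
            score = int(round(l.coverage_fraction * 1000))
            handle.write(
                f"{l.chrom}\t{l.start - 1}\t{l.end}\t{l.name}\t{score}\t{l.strand}\n"
            )
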