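"""Molecular-clock dating of proviral integrations.

At integration time a provirus matches the infecting virus exactly, and its
two LTRs match each other exactly; afterwards it accumulates host-neutral
substitutions.  With a rate of 0.2% per nucleotide per million years, the
integration age in Myr is

    T = D / 0.2        for an internal region against the group consensus,
    T = D / 0.2 / 2    for the 5'LTR-3'LTR comparison (both LTRs diverge),

where D is the percent nucleotide divergence.  Divergence is the uncorrected
p-distance with pairwise deletion of gaps and ambiguous sites; a
Jukes-Cantor correction is available as an option.  Per element, ages come
from the mean of the available (unrounded) region divergences; only regions
retaining at least 90% of their reference length are eligible.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field

from .reference import ProviralReference
from .structure import INTERNAL_REGIONS, RegionIntegrityProfile
from .util import round_half_up

CLOCK_RATE_PCT_PER_MYR = 0.2
BASE_ORDER = "ACGT"
_VALID = set(BASE_ORDER)


def build_consensus(sequences: list[str]) -> str:
    """Column-wise majority consensus of equal-length aligned sequences.

    A column is emitted as a gap when gaps are the strict majority of its
    characters; base ties break by the fixed order A < C < G < T.
    """
    if len(sequences) < 2:
        raise ValueError("consensus requires at least 2 sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("ragged alignment: sequences differ in length")
    out = []
    for col in range(length):
        counts = {b: 0 for b in BASE_ORDER}
        gaps = 0
        for seq in sequences:
            ch = seq[col].upper()
            if ch in _VALID:
                counts[ch] += 1
            else:
                gaps += 1
        total_bases = sum(counts.values())
        if gaps > total_bases:
            out.append("-")
        else:
            out.append(max(BASE_ORDER, key=lambda b: (counts[b], -BASE_ORDER.index(b))))
    return "".join(out)


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites, gaps/ambiguities deleted pairwise."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned lengths")
    compared = diffs = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _VALID and y in _VALID:
            compared += 1
            if x != y:
                diffs += 1
    if compared == 0:
        raise ValueError("no comparable sites between sequences")
    return diffs / compared


def jukes_cantor(p: float) -> float:
    """JC69 distance -(3/4) ln(1 - 4p/3)."""
    if p >= 0.75:
        raise ValueError(f"p-distance {p} saturated under Jukes-Cantor")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def age_from_divergence(
    divergence: float,
    method: str = "internal",
    rate_pct_per_myr: float = CLOCK_RATE_PCT_PER_MYR,
) -> float:
    """Age in Myr from a divergence fraction: T = D/rate (halved for LTR-LTR)."""
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence {divergence} outside [0,1]")
    if rate_pct_per_myr <= 0:
        raise ValueError("clock rate must be positive")
    age = divergence * 100.0 / rate_pct_per_myr
    if method == "ltr-ltr":
        return age / 2.0
    if method == "internal":
        return age
    raise ValueError(f"unknown dating method {method!r}")


@dataclass(frozen=True)
class AgeEstimate:
    """Per-region divergences and the resulting integration age for a locus."""

    locus: str
    region_divergences: dict[str, float] = field(default_factory=dict)
    ltr_ltr_divergence: float | None = None
    method: str = "internal"
    rate_pct_per_myr: float = CLOCK_RATE_PCT_PER_MYR

    @property
    def mean_divergence(self) -> float:
        if self.method == "ltr-ltr":
            if self.ltr_ltr_divergence is None:
                raise ValueError("ltr-ltr estimate lacks an LTR-LTR divergence")
            return self.ltr_ltr_divergence
        values = list(self.region_divergences.values())
        if not values:
            raise ValueError("no region divergences available")
        return sum(values) / len(values)

    @property
    def age_myr(self) -> float:
        return age_from_divergence(
            self.mean_divergence, self.method, self.rate_pct_per_myr
        )


def element_age(
    region_divergences: dict[str, float],
    locus: str = "",
    rate_pct_per_myr: float = CLOCK_RATE_PCT_PER_MYR,
) -> AgeEstimate:
    """Age from the mean of the available (unrounded) region divergences."""
    present = {
        r: d for r, d in region_divergences.items() if d is not None
    }
    if not present:
        raise ValueError("element_age requires at least one region divergence")
    return AgeEstimate(
        locus=locus, region_divergences=present, rate_pct_per_myr=rate_pct_per_myr
    )


def summarize_ages(estimates: list[AgeEstimate]) -> dict[str, float]:
    """Mean/median/min/max of ages in Myr, half-up at 2 decimals."""
    if not estimates:
        raise ValueError("summarize_ages requires at least one estimate")
    ages = [e.age_myr for e in estimates]
    return {
        "mean": round_half_up(statistics.fmean(ages), 2),
        "median": round_half_up(statistics.median(ages), 2),
        "min": round_half_up(min(ages), 2),
        "max": round_half_up(max(ages), 2),
    }


# ---------------------------------------------------------------------------
# Reference-frame alignment of discovered loci and the dating pipeline
# ---------------------------------------------------------------------------

def reference_frame_sequence(record_blocks, genome_seq: str, strand: str, ref_len: int) -> str:
    """Project a locus's aligned bases onto consensus coordinates.

    Returns a string of the reference length with the locus base at each
    covered consensus position and ``-`` elsewhere.  Substitution-only
    block mapping: block columns correspond one-to-one.
    """
    from .simulate import revcomp

    out = ["-"] * ref_len
    for q_start, t_start, length in record_blocks:
        segment = genome_seq[t_start : t_start + length]
        if strand == "-":
            # target ascending maps to descending plus-strand query positions
            segment = revcomp(segment)
        for i, base in enumerate(segment):
            out[q_start + i] = base
    return "".join(out)


def region_alignments(
    records,
    chromosomes: dict[str, str],
    reference: ProviralReference,
    regions: tuple[str, ...] = INTERNAL_REGIONS,
    min_region_cov: float = 0.90,
) -> dict[str, dict[str, str]]:
    """Per-region pseudo-alignments (in consensus frame) of eligible loci.

    A locus region is eligible when its aligned length reaches
    ``min_region_cov`` of the reference region length.
    """
    out: dict[str, dict[str, str]] = {r: {} for r in regions}
    for rec in records:
        frame = reference_frame_sequence(
            rec.blocks, chromosomes[rec.t_name], rec.strand, len(reference)
        )
        name = f"{rec.t_name}:{rec.t_start + 1}-{rec.t_end}"
        for region in regions:
            rs, re_ = reference.region_interval(region)
            slice_ = frame[rs - 1 : re_]
            covered = sum(1 for c in slice_ if c != "-")
            if covered / (re_ - rs + 1) >= min_region_cov:
                out[region][name] = slice_
    return out


def date_loci(
    records,
    chromosomes: dict[str, str],
    reference: ProviralReference,
    min_region_cov: float = 0.90,
    rate_pct_per_myr: float = CLOCK_RATE_PCT_PER_MYR,
    use_jc: bool = False,
) -> list[AgeEstimate]:
    """Date loci from per-region divergence to the group consensus.

    For each internal region, loci retaining >= ``min_region_cov`` of the
    region enter a consensus; each locus's region divergence is its
    p-distance (optionally JC-corrected) to that consensus.  Per-locus ages
    average the available region divergences.
    """
    alignments = region_alignments(
        records, chromosomes, reference, min_region_cov=min_region_cov
    )
    per_locus: dict[str, dict[str, float]] = {}
    for region, seqs in alignments.items():
        if len(seqs) < 2:
            continue
        consensus = build_consensus(list(seqs.values()))
        for name, seq in seqs.items():
            d = p_distance(seq, consensus)
            if use_jc:
                d = jukes_cantor(d)
            per_locus.setdefault(name, {})[region] = d
    return [
        element_age(divs, locus=name, rate_pct_per_myr=rate_pct_per_myr)
        for name, divs in sorted(per_locus.items())
    ]


def ltr_ltr_age(
    record_or_frame,
    chromosomes: dict[str, str] | None,
    reference: ProviralReference,
    min_region_cov: float = 0.90,
    rate_pct_per_myr: float = CLOCK_RATE_PCT_PER_MYR,
) -> AgeEstimate:
    """Date one locus from the divergence between its own two LTRs."""
    if isinstance(record_or_frame, str):
        frame = record_or_frame
        name = "locus"
    else:
        rec = record_or_frame
        frame = reference_frame_sequence(
            rec.blocks, chromosomes[rec.t_name], rec.strand, len(reference)
        )
        name = f"{rec.t_name}:{rec.t_start + 1}-{rec.t_end}"
    s5, e5 = reference.region_interval("5'LTR")
    s3, e3 = reference.region_interval("3'LTR")
    ltr5 = frame[s5 - 1 : e5]
    ltr3 = frame[s3 - 1 : e3]
    for seq, (rs, re_) in ((ltr5, (s5, e5)), (ltr3, (s3, e3))):
        covered = sum(1 for c in seq if c != "-")
        if covered / (re_ - rs + 1) < min_region_cov:
            raise ValueError("both LTRs must retain the minimum coverage for LTR-LTR dating")
    if len(ltr5) != len(ltr3):
        # the two LTR regions of the layout may differ in length by a few bases
        n = min(len(ltr5), len(ltr3))
        ltr5, ltr3 = ltr5[:n], ltr3[:n]
    d = p_distance(ltr5, ltr3)
    return AgeEstimate(
        locus=name, ltr_ltr_divergence=d, method="ltr-ltr",
        rate_pct_per_myr=rate_pct_per_myr,
    )


def write_age_table(estimates: list[AgeEstimate], path) -> None:
    """TSV mirroring the printed age table: per-region D, mean D, age."""
    with open(path, "w") as handle:
        handle.write(
            "locus\t" + "\t".join(f"{r}_div" for r in INTERNAL_REGIONS)
            + "\tmean_div\tage_myr\n"
        )
        for e in estimates:
            cells = [
                f"{e.region_divergences[r]:.3f}" if r in e.region_divergences else "NA"
                for r in INTERNAL_REGIONS
            ]
            handle.write(
                f"{e.locus}\t" + "\t".join(cells)
                + f"\t{e.mean_divergence:.3f}\t{round_half_up(e.age_myr, 2):.2f}\n"
            )
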