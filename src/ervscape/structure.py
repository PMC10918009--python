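"""Per-region structural integrity of proviral loci.

Each locus's covered consensus intervals are intersected with the six-region
layout to give a per-region coverage fraction (aligned reference bases in the
region divided by the region length).  Bases in overlapping ORF junctions
(gag/pro, pro/pol, pol/env) count toward both regions, each fraction being
computed independently.  "Complete deletion" of a region means exactly zero
aligned bases.  A solo LTR is a locus retaining one LTR but no internal
coding sequence at all.
"""

from __future__ import annotations

from dataclasses import dataclass

from .discovery import ProviralLocus
from .reference import REGION_NAMES, ProviralReference

INTERNAL_REGIONS = ("gag", "pro", "pol", "env")


@dataclass(frozen=True)
class RegionIntegrityProfile:
    """Six per-region coverage fractions for one locus."""

    locus: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.fractions) != set(REGION_NAMES):
            raise ValueError(
                f"profile must cover exactly {set(REGION_NAMES)}, got {set(self.fractions)}"
            )
        for region, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{region} fraction {f} outside [0,1]")

    def __getitem__(self, region: str) -> float:
        return self.fractions[region]


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def profile_regions(
    blocks: list[tuple[int, int]],
    reference: ProviralReference,
    locus: str = "",
) -> RegionIntegrityProfile:
    """Coverage fraction of each layout region from covered intervals.

    ``blocks`` are 1-based inclusive consensus intervals.
    """
    for s, e in blocks:
        if s < 1 or e > len(reference) or e < s:
            raise ValueError(f"interval [{s},{e}] outside reference of length {len(reference)}")
    merged = _merge(list(blocks))
    fractions: dict[str, float] = {}
    for region in REGION_NAMES:
        rs, re_ = reference.region_interval(region)
        covered = sum(
            max(0, min(e, re_) - max(s, rs) + 1) for s, e in merged
        )
        fractions[region] = covered / (re_ - rs + 1)
    return RegionIntegrityProfile(locus=locus, fractions=fractions)


def profile_locus(locus: ProviralLocus, reference: ProviralReference) -> RegionIntegrityProfile:
    return profile_regions(list(locus.covered_ref_intervals), reference, locus=locus.name)


def count_complete_deletions(
    profiles: list[RegionIntegrityProfile],
) -> dict[str, int]:
    """Number of loci with exactly zero aligned bases, per region."""
    return {
        region: sum(1 for p in profiles if p[region] == 0.0)
        for region in REGION_NAMES
    }


def detect_solo_ltr(profile: RegionIntegrityProfile, min_ltr_cov: float = 0.5) -> bool:
    """True iff one LTR is substantially present and all internals are absent."""
    ltr = max(profile["5'LTR"], profile["3'LTR"])
    internals_absent = all(profile[r] == 0.0 for r in INTERNAL_REGIONS)
    return ltr >= min_ltr_cov and internals_absent


@dataclass(frozen=True)
class LengthSummary:
    n: int
    mean_bp: int
    min_bp: int
    max_bp: int
    bin_counts: dict[str, int]
    coarse_counts: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.bin_counts.values()) != self.n:
            raise ValueError("bin counts must sum to n")
        if not self.min_bp <= self.mean_bp <= self.max_bp:
            raise ValueError("min <= mean <= max violated")


def summarize_lengths(loci: list[ProviralLocus]) -> LengthSummary:
    """Length and coverage-class summary of a locus catalog.

    The mean is over all loci.  The reported extrema are taken over loci
    without an Insertion flag: nested foreign insertions inflate genomic
    length, so insertion-flagged loci do not define the longest or shortest
    proviral element (all loci are used if every locus carries the flag).
    The coarse classes (>70%, 40-70%, <40%) are on coverage fraction, not
    genomic length.
    """
    if not loci:
        raise ValueError("summarize_lengths requires at least one locus")
    lengths = [l.length for l in loci]
    plain = [l.length for l in loci if "Insertion" not in l.indel_flags] or lengths
    bins: dict[str, int] = {}
    coarse = {">70%": 0, "40%-70%": 0, "<40%": 0}
    for l in loci:
        bins[l.range_bin] = bins.get(l.range_bin, 0) + 1
        pct = l.coverage_fraction * 100
        if pct > 70:
            coarse[">70%"] += 1
        elif pct >= 40:
            coarse["40%-70%"] += 1
        else:
            coarse["<40%"] += 1
    return LengthSummary(
        n=len(loci),
        mean_bp=int(round(sum(lengths) / len(lengths))),
        min_bp=min(plain),
        max_bp=max(plain),
        bin_counts=bins,
        coarse_counts=coarse,
    )


def write_integrity_table(
    profiles: list[RegionIntegrityProfile], path
) -> None:
    """TSV with one row per locus and six percentage columns (2 decimals)."""
    from .util import round_half_up

    with open(path, "w") as handle:
        handle.write("locus\t" + "\t".join(REGION_NAMES) + "\n")
        for p in profiles:
            cells = [
                f"{round_half_up(p[r] * 100, 2):.2f}%" for r in REGION_NAMES
            ]
            handle.write(p.locus + "\t" + "\t".join(cells) + "\n")
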