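"""Chromosomal distribution test for proviral integrations.

Under random integration, the expected number of insertions on a chromosome
is proportional to its nongap length: e = Cl * N / Tl, where Cl is the
chromosome's nongap length, N the total number of observed loci and Tl the
summed nongap length.  A global chi-square goodness-of-fit test compares
observed and expected counts; per-chromosome 1-df tests (that chromosome
against the pooled rest) flag individual enrichment or depletion, reported
with the observed/expected fold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from scipy import stats

from .discovery import ProviralLocus


def nongap_length(seq: str) -> int:
    """Assembly length minus ambiguous (N) bases."""
    up = seq.upper()
    return len(up) - up.count("N")


def nongap_lengths_from_fasta(path) -> dict[str, int]:
    from Bio import SeqIO

    return {rec.id: nongap_length(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def observed_counts(loci: list[ProviralLocus], chroms=None) -> dict[str, int]:
    counts = Counter(l.chrom for l in loci)
    if chroms is not None:
        return {c: counts.get(c, 0) for c in chroms}
    return dict(counts)


def expected_counts(nongap_lengths: dict[str, int], n_total: int) -> dict[str, float]:
    """e_c = Cl_c * N / sum(Cl); the expecteds sum to N exactly."""
    if not nongap_lengths:
        raise ValueError("empty chromosome length map")
    if n_total < 0:
        raise ValueError("total count must be >= 0")
    for chrom, length in nongap_lengths.items():
        if length <= 0:
            raise ValueError(f"nongap length for {chrom} must be > 0, got {length}")
    total = sum(nongap_lengths.values())
    return {c: l * n_total / total for c, l in nongap_lengths.items()}


def chisq_gof(observed: dict[str, int], expected: dict[str, float]):
    """Global goodness-of-fit: statistic, df = k-1, upper-tail p."""
    if set(observed) != set(expected):
        raise ValueError(
            f"observed/expected key mismatch: {set(observed) ^ set(expected)}"
        )
    k = len(observed)
    if k < 2:
        raise ValueError("chi-square test is degenerate with fewer than 2 categories")
    for c, e in expected.items():
        if e <= 0:
            raise ValueError(f"expected count for {c} must be > 0")
    statistic = sum(
        (observed[c] - expected[c]) ** 2 / expected[c] for c in observed
    )
    df = k - 1
    return statistic, df, float(stats.chi2.sf(statistic, df))


def per_chrom_flags(
    observed: dict[str, int],
    expected: dict[str, float],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> dict[str, dict]:
    """Per-chromosome 1-df test (chromosome vs pooled rest) with fold o/e.

    Flags: ``enriched`` if o > e and p < alpha, ``depleted`` if o < e and
    p < alpha, else ``ns``.  BH correction across chromosomes is optional
    (off by default; raw p-values are the headline).
    """
    if set(observed) != set(expected):
        raise ValueError("observed/expected key mismatch")
    n_obs = sum(observed.values())
    n_exp = sum(expected.values())
    results: dict[str, dict] = {}
    pvals: list[float] = []
    chroms = sorted(observed)
    for c in chroms:
        o, e = observed[c], expected[c]
        if e <= 0:
            raise ValueError(f"expected count for {c} must be > 0")
        rest_o, rest_e = n_obs - o, n_exp - e
        statistic = (o - e) ** 2 / e
        if rest_e > 0:
            statistic += (rest_o - rest_e) ** 2 / rest_e
        p = float(stats.chi2.sf(statistic, 1))
        pvals.append(p)
        results[c] = {"observed": o, "expected": e, "fold": o / e, "p": p}
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
        for c, q in zip(chroms, adjusted):
            results[c]["p_adjusted"] = float(q)
    for c in chroms:
        p_use = results[c].get("p_adjusted", results[c]["p"])
        o, e = results[c]["observed"], results[c]["expected"]
        if p_use < alpha and o > e:
            results[c]["flag"] = "enriched"
        elif p_use < alpha and o < e:
            results[c]["flag"] = "depleted"
        else:
            results[c]["flag"] = "ns"
    return results


@dataclass(frozen=True)
class DistributionTestResult:
    observed: dict[str, int]
    expected: dict[str, float]
    statistic: float
    df: int
    p_value: float
    flags: dict[str, dict]


def distribution_test(
    loci: list[ProviralLocus],
    nongap_lengths: dict[str, int],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> DistributionTestResult:
    observed = observed_counts(loci, chroms=nongap_lengths)
    expected = expected_counts(nongap_lengths, sum(observed.values()))
    statistic, df, p = chisq_gof(observed, expected)
    flags = per_chrom_flags(observed, expected, alpha=alpha, bh_correct=bh_correct)
    return DistributionTestResult(observed, expected, statistic, df, p, flags)
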