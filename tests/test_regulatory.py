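"""GREAT-style regulatory domains, LTR-gene association, and ORA."""

import math

import numpy as np
import pytest

from ervscape import (
    GeneModel,
    ProviralLocus,
    associate_ltrs,
    ora_enrichment,
    regulatory_domains,
)
from ervscape.regulatory import basal_domain


def _gene(tss, strand="+", chrom="chr1", gene_id="g1", length=2000):
    if strand == "+":
        start, end = tss, tss + length
    else:
        start, end = tss - length, tss
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     start=start, end=end, exons=((start, end),))


def _locus(start, end, chrom="chr1"):
    return ProviralLocus(
        chrom=chrom, strand="+", start=start, end=end,
        coverage_fraction=0.5, q_gap_fraction=0.0,
        match=0, mismatch=0, q_gap_bases=0, insertion_bases=0,
    )


CHROM_LEN = {"chr1": 10_000_000}


class TestRegulatoryDomains:
    def test_lone_gene_basal_and_extension(self):
        gene = _gene(2_000_000)
        dom = regulatory_domains([gene], chrom_lengths=CHROM_LEN)[0]
        assert dom.basal == (1_995_000, 2_001_000)
        assert dom.extended == (995_000, 3_001_000)

    def test_extension_stops_at_neighbor_basal(self):
        g1, g2 = _gene(100_000), _gene(110_000, gene_id="g2")
        domains = {d.gene_id: d for d in
                   regulatory_domains([g1, g2], chrom_lengths=CHROM_LEN)}
        assert domains["g1"].extended[1] == 105_000  # g2 basal start
        assert domains["g2"].extended[0] == 101_000  # g1 basal end

    def test_clipped_at_chromosome_start(self):
        dom = regulatory_domains([_gene(2_000)], chrom_lengths=CHROM_LEN)[0]
        assert dom.basal[0] == 1
        assert dom.extended[0] == 1

    def test_minus_strand_basal_is_mirrored(self):
        dom_plus = basal_domain(_gene(500_000), 5000, 1000, 10_000_000)
        dom_minus = basal_domain(_gene(500_000, strand="-"), 5000, 1000, 10_000_000)
        assert dom_plus == (495_000, 501_000)
        assert dom_minus == (499_000, 505_000)

    def test_overlapping_basals_get_no_extension_inward(self):
        g1, g2 = _gene(100_000), _gene(103_000, gene_id="g2")
        domains = {d.gene_id: d for d in
                   regulatory_domains([g1, g2], chrom_lengths=CHROM_LEN)}
        assert domains["g1"].extended[1] == domains["g1"].basal[1]
        assert domains["g2"].extended[0] == domains["g2"].basal[0]

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chr9"):
            regulatory_domains([_gene(1000, chrom="chr9")], chrom_lengths=CHROM_LEN)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        """Randomized gene sets: construction equals the all-pairs rule."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        genes = [
            _gene(int(rng.integers(10_000, 9_990_000)),
                  strand=rng.choice(["+", "-"]), gene_id=f"g{i}", length=500)
            for i in range(n)
        ]
        domains = {d.gene_id: d for d in
                   regulatory_domains(genes, chrom_lengths=CHROM_LEN)}
        basals = {g.gene_id: basal_domain(g, 5000, 1000, CHROM_LEN["chr1"])
                  for g in genes}
        for gene in genes:
            bs, be = basals[gene.gene_id]
            left, right = max(1, bs - 1_000_000), min(CHROM_LEN["chr1"], be + 1_000_000)
            for other in genes:
                if other.gene_id == gene.gene_id:
                    continue
                obs, obe = basals[other.gene_id]
                if obe < bs:
                    left = max(left, obe)
                elif obs > be:
                    right = min(right, obs)
                else:
                    left, right = max(left, bs) if obs < bs else left, \
                        min(right, be) if obe > be else right
            dom = domains[gene.gene_id]
            assert dom.extended == (min(left, bs), max(right, be))
            assert dom.extended[0] <= dom.basal[0] <= dom.basal[1] <= dom.extended[1]

    def test_no_extended_domain_crosses_a_neighbor_basal(self):
        rng = np.random.default_rng(99)
        genes = [
            _gene(int(rng.integers(10_000, 9_990_000)), gene_id=f"g{i}", length=500)
            for i in range(30)
        ]
        domains = regulatory_domains(genes, chrom_lengths=CHROM_LEN)
        basals = {g.gene_id: basal_domain(g, 5000, 1000, CHROM_LEN["chr1"])
                  for g in genes}
        for dom in domains:
            for gid, (obs, obe) in basals.items():
                if gid == dom.gene_id:
                    continue
                if obe < dom.basal[0]:
                    assert dom.extended[0] >= obe
                elif obs > dom.basal[1]:
                    assert dom.extended[1] <= obs


class TestAssociateLtrs:
    def test_upstream_30kb_bin(self):
        gene = _gene(2_000_000)
        domains = regulatory_domains([gene], chrom_lengths=CHROM_LEN)
        ltr = _locus(1_969_500, 1_970_500)  # midpoint 30 kb upstream of TSS
        associations = associate_ltrs([ltr], domains, [gene])
        assert len(associations) == 1
        assoc = associations[0]
        assert assoc.distance_bin == "5-50kb"
        assert assoc.orientation == "upstream"
        assert assoc.signed_distance == -30_000

    def test_gene_free_chromosome_has_no_associations(self):
        gene = _gene(2_000_000)
        domains = regulatory_domains([gene], chrom_lengths=CHROM_LEN)
        ltr = _locus(5_000, 6_000, chrom="chr2")
        assert associate_ltrs([ltr], domains, [gene]) == []

    def test_ltr_between_two_domains_gets_both_genes(self):
        g1 = _gene(1_000_000)
        g2 = _gene(1_400_000, gene_id="g2")
        domains = regulatory_domains([g1, g2], chrom_lengths=CHROM_LEN)
        ltr = _locus(1_200_000, 1_201_000)  # inside both extended domains
        associations = associate_ltrs([ltr], domains, [g1, g2])
        assert {a.gene_id for a in associations} == {"g1", "g2"}

    def test_association_equals_all_pairs_interval_check(self):
        rng = np.random.default_rng(7)
        genes = [
            _gene(int(rng.integers(10_000, 9_990_000)), gene_id=f"g{i}", length=500)
            for i in range(20)
        ]
        domains = regulatory_domains(genes, chrom_lengths=CHROM_LEN)
        ltrs = [
            _locus(int(p), int(p) + 800)
            for p in rng.integers(1_000, 9_990_000, size=15)
        ]
        found = {(a.locus, a.gene_id) for a in associate_ltrs(ltrs, domains, genes)}
        brute = {
            (l.name, d.gene_id)
            for l in ltrs
            for d in domains
            if d.chrom == l.chrom
            and l.start <= d.extended[1] and l.end >= d.extended[0]
        }
        assert found == brute


def _hypergeom_oracle(n_universe, k_cat, n_list, overlap):
    """Exact upper-tail enumeration via binomial coefficients."""
    total = math.comb(n_universe, n_list)
    acc = 0
    for x in range(overlap, min(k_cat, n_list) + 1):
        acc += math.comb(k_cat, x) * math.comb(n_universe - k_cat, n_list - x)
    return acc / total


class TestOraEnrichment:
    def test_category_equal_to_universe(self):
        universe = {f"g{i}" for i in range(10)}
        results = ora_enrichment(list(universe)[:4], {"all": set(universe)},
                                 universe, min_size=1)
        assert results[0].enrichment_ratio == pytest.approx(1.0)
        assert results[0].p_value == pytest.approx(1.0)

    def test_perfect_overlap_exact_probability(self):
        # universe 20, category 5, list 5, overlap 5 -> 1/C(20,5)
        universe = {f"g{i}" for i in range(20)}
        category = {f"g{i}" for i in range(5)}
        results = ora_enrichment(sorted(category), {"cat": category}, universe)
        assert results[0].p_value == pytest.approx(1 / 15504, rel=1e-9)

    def test_bh_step_up_toy_vector(self):
        from statsmodels.stats.multitest import multipletests

        _, fdrs, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        assert list(fdrs) == pytest.approx([0.03, 0.03, 0.03])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exact_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_universe = int(rng.integers(10, 26))
        universe = {f"g{i}" for i in range(n_universe)}
        category = set(rng.choice(sorted(universe),
                                  size=int(rng.integers(5, n_universe)), replace=False))
        gene_list = set(rng.choice(sorted(universe),
                                   size=int(rng.integers(1, n_universe)), replace=False))
        results = ora_enrichment(sorted(gene_list), {"cat": category}, universe,
                                 min_size=1, max_size=2000)
        overlap = len(category & gene_list)
        expected = _hypergeom_oracle(n_universe, len(category), len(gene_list), overlap)
        assert results[0].p_value == pytest.approx(expected, rel=1e-9)

    def test_size_filter_and_top_truncation(self):
        universe = {f"g{i}" for i in range(100)}
        categories = {f"c{i}": {f"g{j}" for j in range(i, i + 10)} for i in range(30)}
        categories["tiny"] = {"g0", "g1"}
        results = ora_enrichment(["g0", "g1", "g2"], categories, universe, top=10)
        assert len(results) <= 10
        assert all(r.category != "tiny" for r in results)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_enrichment(["g1"], {"c": {"g1"}}, set())

    def test_gene_list_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_enrichment(["zz"], {"c": {"zz"}}, {"g1"})
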