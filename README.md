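# ervscape

Characterization of endogenous retrovirus (ERV) proviral loci in host
genomes, built around the ERV-K subgroup HML-8 and its 10485-bp
`MER11A-HERVK11-MER11A` consensus model (5'LTR 1–1266, *gag* 1422–3530,
*pro* 3341–4345, *pol* 4303–7032, *env* 6890–9217, 3'LTR 9220–10485).

Endogenous retroviruses are germline-fixed remnants of ancient retroviral
infections.  Cataloging every proviral copy of a family in a genome — where
each sits, how much of the canonical `5'LTR–gag–pro–pol–env–3'LTR` structure
it retains, when it integrated, and which genes its LTRs might regulate —
is the groundwork for studying ERV biology and host–provirus coevolution.
`ervscape` provides that catalog pipeline as a tested Python library with a
thin CLI, for genome annotators and molecular-evolution researchers:

* **discovery** — BLAT-style k-mer seed/chain/extend search of a genome
  against the proviral consensus (11-mers stepped by 5, banded extension),
  or ingestion of precomputed PSL alignments; collinear hits are assembled
  into named loci (`chr:start-end`) with consensus coverage, query-gap
  fraction, and Insertion/Deletion flags;
* **structure** — per-region integrity (aligned bases per region / region
  length) for the six proviral regions, complete-deletion counts, solo-LTR
  detection, length summaries;
* **context** — classification against gene annotation into intergenic /
  intron / exon / exonic&intronic / genic&intergenic;
* **distribution** — expected per-chromosome insertion counts
  `e = Cl · N / Tl` from nongap lengths, a global χ² goodness-of-fit test,
  and per-chromosome enrichment/depletion flags;
* **dating** — molecular-clock integration ages `T = D/0.2` (internal
  region vs group consensus) and `T = D/0.2/2` (LTR–LTR), with D the
  percent p-distance at a neutral rate of 0.2%/nt/Myr;
* **phylogeny** — neighbor-joining trees (p, JC69, K2P distances) with
  bootstrap support and supported-cluster group assignment;
* **regulatory** — GREAT-style basal+extension regulatory domains (5 kb
  up / 1 kb down, ≤1 Mb extension), LTR–gene association with TSS distance
  bins, and hypergeometric over-representation analysis with BH FDR;
* **simulate** — synthetic multi-chromosome genomes with planted proviral
  copies (controlled truncation, divergence, strand, nested insertions) and
  gene models, plus a truth table, so every stage is testable offline.

The package also ships a curated catalog of the 76 chimpanzee (panTro6)
HML-8 proviral loci — locus table, six-region integrity table, and
per-region divergences with integration ages for the 46 datable elements —
used by the summary statistics and the reproduction script.

## Worked example

Plant three proviral copies — a full-length provirus at 5% divergence, a
minus-strand solo 3'LTR, and an internal *gag–pol* fragment at 8% — then
rediscover, profile, and date them:

```python
from ervscape import (InsertionPlan, SearchParams, assemble_loci, generate_reference,
                      kmer_search, plant_loci, profile_locus)
from ervscape.dating import date_loci
from ervscape.structure import count_complete_deletions

reference = generate_reference(seed=7)          # 10485-bp consensus, mirrored LTRs
plans = [
    InsertionPlan(chrom="chr1", position=20_000, divergence=0.05, name="full"),
    InsertionPlan(chrom="chr2", position=30_000, strand="-",
                  kept_intervals=((9220, 10485),), divergence=0.02, name="solo"),
    InsertionPlan(chrom="chr2", position=60_000, kept_intervals=((1422, 7032),),
                  divergence=0.08, name="internal"),
]
bundle = plant_loci(reference, plans, {"chr1": 100_000, "chr2": 90_000},
                    seed=11, out_dir="demo")
records = kmer_search(bundle.chromosomes, reference,
                      SearchParams(min_identity=0.90, min_len=100))
loci = assemble_loci(records, reference)
for locus in loci:
    print(locus.name, locus.strand, f"{locus.coverage_fraction:.2%}", locus.range_bin)

profiles = [profile_locus(l, reference) for l in loci]
print("complete deletions:", count_complete_deletions(profiles))
for age in date_loci(records, bundle.chromosomes, reference):
    print(age.locus, {r: round(d, 3) for r, d in age.region_divergences.items()},
          "->", round(age.age_myr, 2), "Myr")
```

prints

```
chr1:20000-30481 + 99.97% [90%-100%)
chr2:61266-66876 + 53.51% [50%-60%)
chr2:30000-31265 - 12.07% [10%-20%)
complete deletions: {"5'LTR": 1, 'gag': 1, 'pro': 1, 'pol': 1, 'env': 1, "3'LTR": 2}
chr1:20000-30481 {'gag': 0.05, 'pro': 0.054, 'pol': 0.06} -> 27.2 Myr
chr2:61266-66876 {'gag': 0.066, 'pro': 0.064, 'pol': 0.066} -> 32.65 Myr
```

All three planted copies come back at their true coordinates: the
full-length copy covers ~100% of the consensus, the solo LTR covers 12%
(one LTR / 10485), and the internal fragment 54%.  The solo LTR is the only
locus missing every internal region, and only regions retaining ≥90% of
their reference length enter dating.  With just two datable copies the
group consensus is a coarse ancestor proxy, so the two ages shrink toward
each other — dating sharpens as more copies enter the consensus (the test
suite checks <10% relative error with 20 copies per divergence level).

The same stages are available as subcommands of the `ervscape` CLI
(`simulate`, `discover`, `profile`, `context`, `distribution`, `date`,
`phylo`, `regulate`, `run`, `fixtures`); `ervscape run --seed 3 --out out/`
drives the whole pipeline over a simulated bundle and writes per-stage
tables plus a consolidated `summary.json`.

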