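import pytest

from ervscape import InsertionPlan, generate_reference, plant_loci


@pytest.fixture(scope="session")
def reference():
    return generate_reference(seed=7)


@pytest.fixture(scope="session")
def small_bundle(reference, tmp_path_factory):
    """Three chromosomes, five planted copies covering the structural classes."""
    plans = [
        InsertionPlan(chrom="chr1", position=20_000, kept_intervals=((1, 10485),),
                      divergence=0.05, name="full"),
        InsertionPlan(chrom="chr1", position=70_000, kept_intervals=((1, 5000),),
                      divergence=0.0, nested_inserts=((2500, 1500),), name="half_ins",
                      context="intron"),
        InsertionPlan(chrom="chr2", position=30_000, strand="-",
                      kept_intervals=((9220, 10485),), divergence=0.02, name="solo_ltr"),
        InsertionPlan(chrom="chr2", position=60_000, kept_intervals=((1422, 7032),),
                      divergence=0.08, name="internal", context="exonic&intronic"),
        InsertionPlan(chrom="chr3", position=25_000, strand="-",
                      kept_intervals=((1, 3530), (6890, 10485)), divergence=0.03,
                      name="mid_deleted", context="genic&intergenic"),
    ]
    lengths = {"chr1": 100_000, "chr2": 90_000, "chr3": 60_000}
    out = tmp_path_factory.mktemp("bundle")
    return plant_loci(reference, plans, lengths, seed=11, out_dir=out)
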