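"""Packaged reference catalogs of chimpanzee HML-8 proviral loci.

Three curated tables describing the 76 HML-8 (ERV-K) proviral loci of the
chimpanzee reference assembly (panTro6), transcribed with their printed
values preserved exactly:

* ``locus_catalog``   — one row per locus: coordinates, strand, genomic
  length, consensus coverage, query-gap fraction, indel flags, context.
* ``region_integrity`` — per-locus coverage percentage of each of the six
  proviral regions (5'LTR, gag, pro, pol, env, 3'LTR).
* ``integration_ages`` — per-region divergences from the group consensus
  and the resulting molecular-clock ages for the 46 datable elements.

The tables are data, not computation: summary statistics are always
recomputed from them by the analysis modules.  Loaders verify a frozen
sha256 checksum to guard against fixture drift.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from .discovery import ProviralLocus
from .reference import REGION_NAMES
from .structure import RegionIntegrityProfile

_CHECKSUMS = {
    "locus_catalog.tsv": "6e1b67d03fea29d3e364f527f2bb43274f2b8afc068846fd539621072dd906b1",
    "region_integrity.tsv": "44b4f0b44d76978c9d073c10fefd4c97f79aabbfdec17b0416a53473b848c815",
    "integration_ages.tsv": "5351db1a7e37c7dc2540644a102db2c2445264f512179f1bb6eac23c076c277f",
}

FIXTURE_NAMES = ("loci", "integrity", "ages")
_FILES = {
    "loci": "locus_catalog.tsv",
    "integrity": "region_integrity.tsv",
    "ages": "integration_ages.tsv",
}


class FixtureIntegrityError(RuntimeError):
    pass


def _read(filename: str) -> bytes:
    data = resources.files("ervscape.data").joinpath(filename).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise FixtureIntegrityError(
            f"fixture {filename} checksum mismatch: {digest}"
        )
    return data


def _pct(series: pd.Series) -> pd.Series:
    return series.str.rstrip("%").astype(float)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged table by key: 'loci', 'integrity' or 'ages'."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    from io import BytesIO

    df = pd.read_csv(BytesIO(_read(_FILES[name])), sep="\t", keep_default_na=False)
    expected_rows = {"loci": 76, "integrity": 76, "ages": 46}[name]
    if len(df) != expected_rows:
        raise FixtureIntegrityError(
            f"fixture {name} has {len(df)} rows, expected {expected_rows}"
        )
    return df


def catalog_loci() -> list[ProviralLocus]:
    """The locus catalog as ProviralLocus objects (printed values preserved)."""
    df = load_fixture("loci")
    loci: list[ProviralLocus] = []
    for row in df.itertuples():
        flags = frozenset() if row.indel == "NA" else frozenset(row.indel.split(","))
        loci.append(
            ProviralLocus(
                chrom=row.chrom, strand=row.strand,
                start=int(row.start), end=int(row.end),
                coverage_fraction=float(row.coverage_pct.rstrip("%")) / 100.0,
                q_gap_fraction=float(row.qgap_pct.rstrip("%")) / 100.0,
                match=0, mismatch=0, q_gap_bases=0, insertion_bases=0,
                indel_flags=flags,
                context=row.context,
            )
        )
    return loci


def catalog_lengths() -> list[int]:
    return [int(x) for x in load_fixture("loci")["length_bp"]]


def integrity_profiles() -> list[RegionIntegrityProfile]:
    """The region-integrity table as profiles (fractions in [0, 1])."""
    df = load_fixture("integrity")
    cols = dict(zip(
        REGION_NAMES,
        ["ltr5_pct", "gag_pct", "pro_pct", "pol_pct", "env_pct", "ltr3_pct"],
    ))
    profiles = []
    for row in df.itertuples(index=False):
        fractions = {
            region: float(getattr(row, col).rstrip("%")) / 100.0
            for region, col in cols.items()
        }
        profiles.append(RegionIntegrityProfile(locus=row.locus, fractions=fractions))
    return profiles


def age_divergences() -> list[dict]:
    """Per-element region divergences from the age table (NA dropped)."""
    df = load_fixture("ages")
    out = []
    for row in df.itertuples(index=False):
        divergences = {}
        for region, col in (("gag", "gag_div"), ("pro", "pro_div"),
                            ("pol", "pol_div"), ("env", "env_div")):
            value = getattr(row, col)
            if not (isinstance(value, float) and np.isnan(value)) and value != "NA":
                divergences[region] = float(value)
        out.append({"locus": row.locus, "divergences": divergences})
    return out
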