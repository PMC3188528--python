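import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from riteseq import (
    BarcodeEntry,
    Catalog,
    EntryStatus,
    PrimerSet,
    Sample,
    SampleSheet,
    TagKind,
)
from riteseq.catalog import Antibody


@pytest.fixture()
def primers() -> PrimerSet:
    return PrimerSet()


@pytest.fixture()
def chip_sheet() -> SampleSheet:
    """Minimal ChIP design: HA/T7 at t1 and t3."""
    return SampleSheet(
        [
            Sample("AACC", "HA_t1", Antibody.HA, "t1"),
            Sample("AAGG", "T7_t1", Antibody.T7, "t1"),
            Sample("CCAA", "HA_t3", Antibody.HA, "t3"),
            Sample("CCTT", "T7_t3", Antibody.T7, "t3"),
        ]
    )


@pytest.fixture()
def tiny_catalog() -> Catalog:
    """Three strains with distinct seed prefixes, both tags each."""
    rows = [
        ("s1", "GEN1", "ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA", EntryStatus.ACTIVE),
        ("s2", "GEN2", "GGTTCCAACCGGTTAACCGG", "AATTGGCCAATTGGCCAATT", EntryStatus.ACTIVE),
        ("s3", "GEN3", "CTCTCTCTCTAGAGAGAGAG", "GAGAGAGAGATCTCTCTCTC", EntryStatus.ACTIVE),
    ]
    entries = []
    for sid, gene, up, down, status in rows:
        entries.append(BarcodeEntry(sid, gene, TagKind.UP, up, status))
        entries.append(BarcodeEntry(sid, gene, TagKind.DOWN, down, status))
    return Catalog(entries)


def make_read(primers: PrimerSet, index: str, tag: TagKind, barcode: str, filler: str = "") -> str:
    return index + primers.primer(tag) + barcode + filler


@pytest.fixture()
def read_builder(primers):
    def build(index: str, tag: TagKind, barcode: str, filler: str = "") -> str:
        return make_read(primers, index, tag, barcode, filler)

    return build


@pytest.fixture(autouse=True)
def _quiet_primer_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
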