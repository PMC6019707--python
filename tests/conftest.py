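"""Shared helpers: compact builders for alleles, calls, and tiny cohorts."""

from pathlib import Path

import pytest

from hlatrio.cohort_io import GenotypeCall, SampleRecord, TrioCohort
from hlatrio.nomenclature import parse_allele

DATA_DIR = Path(__file__).parent / "data"


def allele(text):
    return parse_allele(text)


def call(sample_id, locus, method, a1, a2):
    return GenotypeCall(sample_id, locus, method, (parse_allele(a1), parse_allele(a2)))


def trio_cohort(child, mother, father, locus="A", method="m", family="fam1"):
    """One-family cohort from three (allele1, allele2) string pairs."""
    cohort = TrioCohort(loci=[locus])
    cohort.samples = [
        SampleRecord("c1", family, "child"),
        SampleRecord("m1", family, "mother"),
        SampleRecord("f1", family, "father"),
    ]
    for sid, pair in (("c1", child), ("m1", mother), ("f1", father)):
        cohort.add_call(call(sid, locus, method, *pair))
    return cohort


@pytest.fixture
def golden_nomenclature_path():
    return DATA_DIR / "nomenclature_golden.tsv"
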