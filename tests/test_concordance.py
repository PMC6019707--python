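"""Trio matching, descent accuracy, transmission phasing, and agreement."""

import itertools
import random

import pytest

from conftest import call, trio_cohort
from hlatrio.cohort_io import GenotypeCall, SampleRecord, TrioCohort
from hlatrio.concordance import (
    classify_transmission,
    descent_accuracy,
    match_trio_locus,
    method_agreement,
)
from hlatrio.nomenclature import AlleleName

# ---------------------------------------------------------------------------
# independent oracles


def oracle_n_eq(child, mother, father):
    """Exhaustive enumeration over transmitted-allele choices.

    Each parent transmits one of its two alleles; the child's two slots are
    paired with the two transmitted alleles in either order; count matches.
    """
    best = 0
    for mi, fi in itertools.product(range(2), range(2)):
        transmitted = (mother[mi], father[fi])
        for order in itertools.permutations(range(2)):
            n = sum(child[s] == transmitted[order[s]] for s in range(2))
            best = max(best, n)
    return best


def oracle_pair_agreement(pa, pb):
    """Maximum over slot bijections of the number of equal alleles."""
    return max(
        sum(pa[i] == pb[p[i]] for i in range(2))
        for p in itertools.permutations(range(2))
    )


def _geno(sample, pair, method="m", locus="A"):
    alleles = tuple(AlleleName("A", (f"{x:02d}",)) for x in pair)
    return GenotypeCall(sample, locus, method, alleles)


# ---------------------------------------------------------------------------
# match_trio_locus


@pytest.mark.parametrize(
    "child, mother, father, n_eq, ambiguous",
    [
        # fully consistent trio: one allele from each parent
        (("A*02:01", "A*01:01"), ("A*02:01", "A*03:01"), ("A*01:01", "A*11:01"), 2, False),
        # homozygous child, only the mother carries the allele
        (("A*02:01", "A*02:01"), ("A*02:01", "A*03:01"), ("A*24:02", "A*11:01"), 1, False),
        # both child alleles present in the mother only: one-per-parent cap
        (("A*02:01", "A*03:01"), ("A*02:01", "A*03:01"), ("A*24:02", "A*11:01"), 1, True),
        # nothing explained
        (("A*02:01", "A*03:01"), ("A*24:02", "A*26:01"), ("A*30:01", "A*11:01"), 0, False),
        # homozygous child explained twice only when both parents carry it
        (("A*02:01", "A*02:01"), ("A*02:01", "A*03:01"), ("A*02:01", "A*11:01"), 2, False),
    ],
)
def test_match_trio_locus(child, mother, father, n_eq, ambiguous):
    cohort = trio_cohort(child, mother, father)
    match = match_trio_locus(
        cohort.get_call("m", "c1", "A"),
        cohort.get_call("m", "m1", "A"),
        cohort.get_call("m", "f1", "A"),
        resolution=4,
    )
    assert match.n_eq_locus == n_eq
    assert match.ambiguous is ambiguous
    assert len(match.assignment) == n_eq


def test_match_respects_resolution():
    cohort = trio_cohort(
        ("A*02:01:01:01", "A*01:01"), ("A*02:01:01:02", "A*03:01"), ("A*01:01", "A*11:01")
    )
    args = [cohort.get_call("m", s, "A") for s in ("c1", "m1", "f1")]
    assert match_trio_locus(*args, resolution=8).n_eq_locus == 1  # 8-digit mismatch
    assert match_trio_locus(*args, resolution=4).n_eq_locus == 2  # merged after reduction


def test_match_locus_mismatch_raises():
    with pytest.raises(ValueError, match="locus"):
        match_trio_locus(
            call("c", "A", "m", "A*02:01", "A*01:01"),
            call("mo", "A", "m", "A*02:01", "A*01:01"),
            call("fa", "B", "m", "B*07:02", "B*07:02"),
        )


def test_lax_mode_allows_both_alleles_from_one_parent():
    cohort = trio_cohort(
        ("A*02:01", "A*03:01"), ("A*02:01", "A*03:01"), ("A*24:02", "A*11:01")
    )
    args = [cohort.get_call("m", s, "A") for s in ("c1", "m1", "f1")]
    assert match_trio_locus(*args, require_distinct_parents=True).n_eq_locus == 1
    assert match_trio_locus(*args, require_distinct_parents=False).n_eq_locus == 2


def test_oracle_equivalence_exhaustive_three_alleles():
    """All 216 trios over the 6 unordered genotypes of a 3-allele alphabet."""
    genotypes = list(itertools.combinations_with_replacement(range(3), 2))
    assert len(genotypes) == 6
    count = 0
    for child, mother, father in itertools.product(genotypes, repeat=3):
        match = match_trio_locus(
            _geno("c", child), _geno("mo", mother), _geno("fa", father), resolution=2
        )
        assert match.n_eq_locus == oracle_n_eq(child, mother, father)
        count += 1
    assert count == 216


def test_oracle_equivalence_random_ten_alleles():
    rng = random.Random(42)
    for _ in range(2000):
        child, mother, father = (
            tuple(rng.randrange(10) for _ in range(2)) for _ in range(3)
        )
        match = match_trio_locus(
            _geno("c", child), _geno("mo", mother), _geno("fa", father), resolution=2
        )
        assert match.n_eq_locus == oracle_n_eq(child, mother, father)


# ---------------------------------------------------------------------------
# descent_accuracy


def test_da_fully_consistent_trio():
    cohort = trio_cohort(("A*02:01", "A*01:01"), ("A*02:01", "A*03:01"), ("A*01:01", "A*11:01"))
    report = descent_accuracy(cohort, "m")
    assert report.da_overall == 1.0
    assert report.n_alleles == 2 == report.n_children * 2 * len(report.loci)


def test_da_five_of_six_alleles_explained():
    """1 trio, 3 loci, five child alleles explained and one not -> 5/6."""
    cohort = TrioCohort(loci=["A", "B", "C"])
    cohort.samples = [
        SampleRecord("c1", "fam1", "child"),
        SampleRecord("m1", "fam1", "mother"),
        SampleRecord("f1", "fam1", "father"),
    ]
    consistent = {
        "A": (("A*02:01", "A*01:01"), ("A*02:01", "A*03:01"), ("A*01:01", "A*11:01")),
        "B": (("B*07:02", "B*08:01"), ("B*07:02", "B*15:01"), ("B*08:01", "B*44:02")),
        # child B-slot fine; one C child allele (C*05:01) is unexplained
        "C": (("C*07:01", "C*05:01"), ("C*07:01", "C*04:01"), ("C*03:03", "C*06:02")),
    }
    for locus, (child, mother, father) in consistent.items():
        cohort.add_call(call("c1", locus, "m", *child))
        cohort.add_call(call("m1", locus, "m", *mother))
        cohort.add_call(call("f1", locus, "m", *father))
    report = descent_accuracy(cohort, "m")
    assert (report.n_eq, report.n_alleles) == (5, 6)
    assert report.da_overall == pytest.approx(5 / 6)
    assert report.da_per_locus == {"A": 1.0, "B": 1.0, "C": 0.5}


def test_da_excludes_untyped_locus_and_incomplete_family():
    cohort = trio_cohort(("A*02:01", "A*01:01"), ("A*02:01", "A*03:01"), ("A*01:01", "A*11:01"))
    cohort.loci = ["A", "B"]  # nobody typed at B
    cohort.samples.append(SampleRecord("x1", "fam2", "father"))  # incomplete family
    report = descent_accuracy(cohort, "m")
    assert report.excluded == [("fam1", "B")]
    assert report.incomplete_families == ["fam2"]
    assert report.n_alleles == 2


def test_da_no_evaluable_family_raises():
    cohort = trio_cohort(("A*02:01", "A*01:01"), ("A*02:01", "A*03:01"), ("A*01:01", "A*11:01"))
    with pytest.raises(ValueError, match="no evaluable family"):
        descent_accuracy(cohort, "absent-method")


def test_da_invariant_under_family_relabelling():
    rng = random.Random(7)
    cohort = TrioCohort(loci=["A"])
    pools = [f"A*{i:02d}:01" for i in range(1, 6)]
    for i in range(10):
        fam = f"fam{i}"
        cohort.samples += [
            SampleRecord(f"c{i}", fam, "child"),
            SampleRecord(f"m{i}", fam, "mother"),
            SampleRecord(f"f{i}", fam, "father"),
        ]
        for sid in (f"c{i}", f"m{i}", f"f{i}"):
            cohort.add_call(call(sid, "A", "m", rng.choice(pools), rng.choice(pools)))
    base = descent_accuracy(cohort, "m")
    shuffled = TrioCohort(samples=list(reversed(cohort.samples)), typings=dict(cohort.typings), loci=["A"])
    assert descent_accuracy(shuffled, "m").da_overall == base.da_overall


# ---------------------------------------------------------------------------
# classify_transmission


def test_transmission_fully_consistent_trio():
    cohort = trio_cohort(("A*02:01", "A*01:01"), ("A*02:01", "A*03:01"), ("A*01:01", "A*11:01"))
    phase = classify_transmission(cohort, "fam1", "m")
    mother = cohort.get_call("m", "m1", "A")
    t = phase.transmitted[("m1", "A")]
    assert mother.alleles[t].fields == ("02", "01")
    assert phase.slot_class("m1", "A", 1 - t) == "non_transmitted"
    father = cohort.get_call("m", "f1", "A")
    assert father.alleles[phase.transmitted[("f1", "A")]].fields == ("01", "01")


def test_transmission_homozygous_mother_tie_break():
    cohort = trio_cohort(("A*02:01", "A*01:01"), ("A*02:01", "A*02:01"), ("A*01:01", "A*11:01"))
    phase = classify_transmission(cohort, "fam1", "m")
    assert phase.transmitted[("m1", "A")] == 0  # first slot by tie-break
    assert ("m1", "A") in phase.ambiguous


def test_transmission_inconsistent_locus_unresolved():
    cohort = trio_cohort(("A*05:01", "A*06:01"), ("A*02:01", "A*03:01"), ("A*01:01", "A*11:01"))
    phase = classify_transmission(cohort, "fam1", "m")
    assert phase.transmitted[("m1", "A")] is None
    assert phase.slot_class("f1", "A", 0) == "unresolved"


def test_transmission_requires_complete_family():
    cohort = trio_cohort(("A*02:01", "A*01:01"), ("A*02:01", "A*03:01"), ("A*01:01", "A*11:01"))
    cohort.samples = cohort.samples[:2]
    with pytest.raises(ValueError, match="complete"):
        classify_transmission(cohort, "fam1", "m")


# ---------------------------------------------------------------------------
# method_agreement


def two_method_cohort(pairs_a, pairs_b, locus="A"):
    """Three-member family cohort with per-sample pairs for two methods."""
    cohort = TrioCohort(loci=[locus])
    cohort.samples = [
        SampleRecord("c1", "fam1", "child"),
        SampleRecord("m1", "fam1", "mother"),
        SampleRecord("f1", "fam1", "father"),
    ]
    for sid in ("c1", "m1", "f1"):
        cohort.add_call(call(sid, locus, "x", *pairs_a[sid]))
        cohort.add_call(call(sid, locus, "y", *pairs_b[sid]))
    return cohort


def test_ma_identical_typings():
    pairs = {
        "c1": ("A*02:01", "A*01:01"),
        "m1": ("A*02:01", "A*03:01"),
        "f1": ("A*01:01", "A*11:01"),
    }
    report = method_agreement(two_method_cohort(pairs, pairs), "x", "y")
    assert report.ma_total == 1.0
    assert report.ma_t == 1.0 and report.ma_nt == 1.0
    assert all(v == 2 for v in report.per_individual_agree.values())


def test_ma_single_mismatch():
    pairs_a = {"c1": ("A*02:01", "A*01:01"), "m1": ("A*02:01", "A*03:01"), "f1": ("A*01:01", "A*11:01")}
    pairs_b = dict(pairs_a, c1=("A*02:01", "A*03:01"))
    report = method_agreement(two_method_cohort(pairs_a, pairs_b), "x", "y")
    assert report.n_agree == 5
    assert report.ma_total == pytest.approx(5 / 6)
    assert report.per_individual_agree["c1"] == 1


def test_ma_multiset_semantics():
    """{a,a} vs {a,b} agrees on exactly one allele, not two."""
    pairs_a = {"c1": ("A*02:01", "A*02:01"), "m1": ("A*02:01", "A*03:01"), "f1": ("A*01:01", "A*11:01")}
    pairs_b = dict(pairs_a, c1=("A*02:01", "A*01:01"))
    report = method_agreement(two_method_cohort(pairs_a, pairs_b), "x", "y")
    assert report.per_individual_agree["c1"] == 1


def test_ma_agreement_matches_pairing_oracle():
    """Multiset intersection equals the brute-force pairing maximum on all
    pair-of-pairs over a 3-allele alphabet."""
    genotypes = list(itertools.combinations_with_replacement(range(3), 2))
    for ga, gb in itertools.product(genotypes, repeat=2):
        cohort = TrioCohort(loci=["A"])
        cohort.samples = [SampleRecord("s1", "famX", "father")]
        cohort.add_call(_geno("s1", ga, method="x"))
        cohort.add_call(_geno("s1", gb, method="y"))
        report = method_agreement(cohort, "x", "y", resolution=2)
        assert report.n_agree == oracle_pair_agreement(ga, gb)


def test_ma_symmetric_and_excludes_partial_samples():
    pairs_a = {"c1": ("A*02:01", "A*01:01"), "m1": ("A*02:01", "A*03:01"), "f1": ("A*01:01", "A*11:01")}
    pairs_b = dict(pairs_a, m1=("A*24:02", "A*26:01"))
    cohort = two_method_cohort(pairs_a, pairs_b)
    # an extra sample typed by one method only
    cohort.samples.append(SampleRecord("s9", "fam9", "father"))
    cohort.add_call(call("s9", "A", "x", "A*02:01", "A*02:01"))
    fwd = method_agreement(cohort, "x", "y")
    rev = method_agreement(cohort, "y", "x")
    assert fwd.ma_total == rev.ma_total
    assert fwd.excluded_samples == ["s9"]
    assert fwd.n_population == 3
    assert sum(fwd.per_individual_agree.values()) == fwd.n_agree


def test_ma_identical_method_labels_rejected():
    pairs = {"c1": ("A*02:01", "A*01:01"), "m1": ("A*02:01", "A*03:01"), "f1": ("A*01:01", "A*11:01")}
    with pytest.raises(ValueError, match="differ"):
        method_agreement(two_method_cohort(pairs, pairs), "x", "x")


def test_ma_slot_class_accounting():
    """Transmitted + non-transmitted + unresolved slots cover everything."""
    pairs_a = {"c1": ("A*02:01", "A*01:01"), "m1": ("A*02:01", "A*03:01"), "f1": ("A*01:01", "A*11:01")}
    pairs_b = dict(pairs_a, f1=("A*24:02", "A*26:01"))
    report = method_agreement(two_method_cohort(pairs_a, pairs_b), "x", "y")
    total_slots = report.n_population * 2 * len(report.loci)
    assert report.n_slots_t + report.n_slots_nt + report.n_slots_unresolved == total_slots
    # the child's two slots plus one transmitted slot per parent
    assert report.n_slots_t == 4
    assert report.n_slots_nt == 2
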