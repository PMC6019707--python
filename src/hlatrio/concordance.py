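"""Trio Mendelian consistency and the two accuracy statistics.

Descent Accuracy (DA) exploits the pedigree in place of a curated gold
standard: each child carries two alleles per locus, one inherited from each
parent, so every child allele should be *explained* by an allele typed in
the assigned parent.  With ``N_eq`` the number of explained child alleles,

    DA = N_eq / N_alleles,      N_alleles = N_children * 2 * |loci|

Method Agreement (MA) compares two typing methods over the whole
population: the number of identically typed alleles (multiset intersection
of the two unordered pairs, per sample and locus) over
``N_population * 2 * |loci|``.  MA_T / MA_NT restrict both numerator and
denominator to allele slots classified as transmitted / non-transmitted by
the trio phasing of a reference method.

All comparisons happen after explicit reduction to a working resolution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .cohort_io import GenotypeCall, SampleRecord, TrioCohort
from .nomenclature import AlleleName, reduce_allele

__all__ = [
    "TrioMatch",
    "DAReport",
    "TransmissionPhase",
    "MAReport",
    "match_trio_locus",
    "descent_accuracy",
    "classify_transmission",
    "method_agreement",
]

PARENT_ROLES = ("mother", "father")


def _key(a: AlleleName, resolution: int, ignore_suffix: bool):
    r = reduce_allele(a, resolution)
    return (r.gene, r.fields) if ignore_suffix else (r.gene, r.fields, r.suffix)


@dataclass
class TrioMatch:
    """Result of matching one child's locus genotype against its parents.

    ``assignment`` maps matched child allele slots (0/1) to
    ``(parent_role, parent_slot)`` for one maximal consistent assignment;
    ``ambiguous`` flags that several distinct maximal assignments exist.
    """

    family_id: str
    locus: str
    n_eq_locus: int
    assignment: dict[int, tuple[str, int]] = field(default_factory=dict)
    ambiguous: bool = False


def match_trio_locus(
    child: GenotypeCall,
    mother: GenotypeCall,
    father: GenotypeCall,
    resolution: int = 4,
    ignore_suffix: bool = True,
    family_id: str = "",
    require_distinct_parents: bool = True,
) -> TrioMatch:
    """Maximal Mendelian-consistent assignment of child alleles to parents.

    The two child alleles are assigned to two *different* parents (a child
    inherits one allele from each progenitor); ``n_eq_locus`` is the
    maximum, over both parent orders and over the choice of matching
    parent allele slot, of the number of child alleles equal (at the
    working resolution) to an allele of the assigned parent.  The first
    maximal configuration in the canonical enumeration (parent order x
    child-slot-0 choice x child-slot-1 choice, unmatched last) is
    recorded; ``ambiguous`` is set when several distinct maxima exist.

    With ``require_distinct_parents=False`` each child allele may instead
    be explained by *either* parent independently (sensitivity analysis).
    """
    if not (child.locus == mother.locus == father.locus):
        raise ValueError(
            f"locus mismatch across trio: child={child.locus} "
            f"mother={mother.locus} father={father.locus}"
        )
    ckeys = [_key(a, resolution, ignore_suffix) for a in child.alleles]
    parents = {
        "mother": [_key(a, resolution, ignore_suffix) for a in mother.alleles],
        "father": [_key(a, resolution, ignore_suffix) for a in father.alleles],
    }

    def slot_options(child_key, role):
        # matching parent slots in slot order, then the unmatched option
        opts = [(role, s) for s in (0, 1) if parents[role][s] == child_key]
        opts.append(None)
        return opts

    def signature(cfg):
        # configurations differing only in which of two identical child
        # slots is used are the same assignment
        return tuple(sorted((ckeys[s], role, pslot) for s, (role, pslot) in cfg.items()))

    best: dict[int, tuple[str, int]] = {}
    signatures: set = set()
    best_n = -1
    if require_distinct_parents:
        orders = [("mother", "father"), ("father", "mother")]
    else:
        # each child slot free to use either parent; enumerate role per slot
        orders = [(r0, r1) for r0 in PARENT_ROLES for r1 in PARENT_ROLES]
    for role0, role1 in orders:
        for opt0 in slot_options(ckeys[0], role0):
            for opt1 in slot_options(ckeys[1], role1):
                cfg = {}
                if opt0 is not None:
                    cfg[0] = opt0
                if opt1 is not None:
                    cfg[1] = opt1
                n = len(cfg)
                if n > best_n:
                    best, best_n = cfg, n
                    signatures = {signature(cfg)}
                elif n == best_n:
                    signatures.add(signature(cfg))
    return TrioMatch(
        family_id=family_id,
        locus=child.locus,
        n_eq_locus=best_n,
        assignment=best,
        ambiguous=len(signatures) > 1,
    )


@dataclass
class DAReport:
    """Descent-accuracy counts and ratios for one method x resolution."""

    method: str
    resolution: int
    n_eq: int
    n_alleles: int
    n_children: int
    loci: list[str]
    da_overall: float
    da_per_locus: dict[str, float]
    n_eq_per_locus: dict[str, int]
    n_children_per_locus: dict[str, int]
    excluded: list[tuple[str, str]] = field(default_factory=list)
    incomplete_families: list[str] = field(default_factory=list)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "method": self.method,
                "resolution": self.resolution,
                "locus": locus,
                "n_eq": self.n_eq_per_locus[locus],
                "n_alleles": 2 * self.n_children_per_locus[locus],
                "da": self.da_per_locus[locus],
            }
            for locus in self.loci
        ]
        rows.append(
            {
                "method": self.method,
                "resolution": self.resolution,
                "locus": "overall",
                "n_eq": self.n_eq,
                "n_alleles": self.n_alleles,
                "da": self.da_overall,
            }
        )
        return pd.DataFrame(rows, columns=["method", "resolution", "locus", "n_eq", "n_alleles", "da"])

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "resolution": self.resolution,
            "n_eq": self.n_eq,
            "n_alleles": self.n_alleles,
            "n_children": self.n_children,
            "loci": list(self.loci),
            "da_overall": self.da_overall,
            "da_per_locus": dict(self.da_per_locus),
            "excluded_family_loci": [list(t) for t in self.excluded],
            "incomplete_families": list(self.incomplete_families),
        }


def descent_accuracy(
    cohort: TrioCohort,
    method: str,
    resolution: int = 4,
    ignore_suffix: bool = True,
    require_distinct_parents: bool = True,
) -> DAReport:
    """DA = N_eq / (N_children * 2 * |loci|) over complete, fully typed trios.

    A family enters the count for a locus only when all three members have
    a call for the method at that locus; exclusions are reported, never
    silent.
    """
    complete = cohort.complete_families()
    incomplete = cohort.incomplete_families()
    n_eq_per_locus: Counter = Counter()
    n_children_per_locus: Counter = Counter()
    excluded: list[tuple[str, str]] = []
    evaluated_children: set[str] = set()
    for fam_id in sorted(complete):
        members = complete[fam_id]
        for locus in cohort.loci:
            calls = {
                role: cohort.get_call(method, members[role].sample_id, locus)
                for role in ("child", "mother", "father")
            }
            if any(c is None for c in calls.values()):
                excluded.append((fam_id, locus))
                continue
            match = match_trio_locus(
                calls["child"],
                calls["mother"],
                calls["father"],
                resolution=resolution,
                ignore_suffix=ignore_suffix,
                family_id=fam_id,
                require_distinct_parents=require_distinct_parents,
            )
            n_eq_per_locus[locus] += match.n_eq_locus
            n_children_per_locus[locus] += 1
            evaluated_children.add(members["child"].sample_id)
    n_alleles = 2 * sum(n_children_per_locus[l] for l in cohort.loci)
    if n_alleles == 0:
        raise ValueError(
            f"no evaluable family for method {method!r}: "
            f"{len(complete)} complete families, {len(excluded)} locus exclusions"
        )
    n_eq = sum(n_eq_per_locus[l] for l in cohort.loci)
    return DAReport(
        method=method,
        resolution=resolution,
        n_eq=n_eq,
        n_alleles=n_alleles,
        n_children=len(evaluated_children),
        loci=list(cohort.loci),
        da_overall=n_eq / n_alleles,
        da_per_locus={
            l: (n_eq_per_locus[l] / (2 * n_children_per_locus[l]))
            if n_children_per_locus[l]
            else float("nan")
            for l in cohort.loci
        },
        n_eq_per_locus={l: n_eq_per_locus[l] for l in cohort.loci},
        n_children_per_locus={l: n_children_per_locus[l] for l in cohort.loci},
        excluded=excluded,
        incomplete_families=incomplete,
    )


@dataclass
class TransmissionPhase:
    """Per parent x locus: which allele slot was transmitted to the child.

    ``transmitted[(sample_id, locus)]`` is the transmitted slot index, or
    ``None`` when unresolved (parent unmatched, missing calls, or an
    inconsistent locus); ``ambiguous`` flags tie-broken assignments.
    """

    family_id: str
    transmitted: dict[tuple[str, str], int | None] = field(default_factory=dict)
    ambiguous: set[tuple[str, str]] = field(default_factory=set)

    def slot_class(self, sample_id: str, locus: str, slot: int) -> str:
        """'transmitted' | 'non_transmitted' | 'unresolved' for a parent slot."""
        t = self.transmitted.get((sample_id, locus))
        if t is None:
            return "unresolved"
        return "transmitted" if slot == t else "non_transmitted"


def classify_transmission(
    cohort: TrioCohort,
    family_id: str,
    method: str,
    resolution: int = 4,
    ignore_suffix: bool = True,
) -> TransmissionPhase:
    """Phase each parent's alleles into transmitted / non-transmitted slots.

    Uses the tie-broken maximal assignment of :func:`match_trio_locus`; a
    parent with no assigned child allele at a locus is unresolved there.
    """
    members = cohort.families().get(family_id)
    if members is None or len(members) < 3:
        raise ValueError(f"family {family_id!r} is not a complete trio")
    phase = TransmissionPhase(family_id=family_id)
    for locus in cohort.loci:
        calls = {
            role: cohort.get_call(method, members[role].sample_id, locus)
            for role in ("child", "mother", "father")
        }
        parent_ids = {r: members[r].sample_id for r in PARENT_ROLES}
        if any(c is None for c in calls.values()):
            for role in PARENT_ROLES:
                phase.transmitted[(parent_ids[role], locus)] = None
            continue
        match = match_trio_locus(
            calls["child"],
            calls["mother"],
            calls["father"],
            resolution=resolution,
            ignore_suffix=ignore_suffix,
            family_id=family_id,
        )
        assigned = {role: None for role in PARENT_ROLES}
        for _child_slot, (role, parent_slot) in match.assignment.items():
            assigned[role] = parent_slot
        for role in PARENT_ROLES:
            key = (parent_ids[role], locus)
            phase.transmitted[key] = assigned[role]
            if match.ambiguous and assigned[role] is not None:
                phase.ambiguous.add(key)
    return phase


@dataclass
class MAReport:
    """Method-agreement counts and ratios for one method pair."""

    methods: tuple[str, str]
    resolution: int
    n_population: int
    loci: list[str]
    n_agree: int
    ma_total: float
    ma_t: float
    ma_nt: float
    ma_per_locus: dict[str, float]
    ma_t_per_locus: dict[str, float]
    ma_nt_per_locus: dict[str, float]
    per_individual_agree: dict[str, int]
    n_slots_t: int = 0
    n_slots_nt: int = 0
    n_slots_unresolved: int = 0
    excluded_samples: list[str] = field(default_factory=list)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "methods": "|".join(self.methods),
                "resolution": self.resolution,
                "locus": locus,
                "ma_total": self.ma_per_locus[locus],
                "ma_t": self.ma_t_per_locus[locus],
                "ma_nt": self.ma_nt_per_locus[locus],
            }
            for locus in self.loci
        ]
        rows.append(
            {
                "methods": "|".join(self.methods),
                "resolution": self.resolution,
                "locus": "overall",
                "ma_total": self.ma_total,
                "ma_t": self.ma_t,
                "ma_nt": self.ma_nt,
            }
        )
        return pd.DataFrame(
            rows, columns=["methods", "resolution", "locus", "ma_total", "ma_t", "ma_nt"]
        )

    def to_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "resolution": self.resolution,
            "n_population": self.n_population,
            "loci": list(self.loci),
            "n_agree": self.n_agree,
            "ma_total": self.ma_total,
            "ma_t": self.ma_t,
            "ma_nt": self.ma_nt,
            "ma_per_locus": dict(self.ma_per_locus),
            "n_slots": {
                "transmitted": self.n_slots_t,
                "non_transmitted": self.n_slots_nt,
                "unresolved": self.n_slots_unresolved,
            },
            "per_individual_agree": dict(self.per_individual_agree),
            "excluded_samples": list(self.excluded_samples),
        }

    def agreement_histogram(self) -> pd.DataFrame:
        """Individuals per identically-typed-allele count (0..2*|loci|)."""
        counts = Counter(self.per_individual_agree.values())
        return pd.DataFrame(
            [
                {"n_identical_alleles": k, "n_individuals": counts.get(k, 0)}
                for k in range(2 * len(self.loci) + 1)
            ]
        )


def _slot_agreement(pair_a, pair_b, resolution, ignore_suffix) -> list[bool]:
    """Which slots of pair_a are matched in a maximum multiset matching
    against pair_b (slots consumed in slot order — deterministic)."""
    remaining = Counter(_key(b, resolution, ignore_suffix) for b in pair_b)
    agree = []
    for a in pair_a:
        k = _key(a, resolution, ignore_suffix)
        if remaining[k] > 0:
            remaining[k] -= 1
            agree.append(True)
        else:
            agree.append(False)
    return agree


def method_agreement(
    cohort: TrioCohort,
    method_a: str,
    method_b: str,
    resolution: int = 4,
    ignore_suffix: bool = True,
    phase_reference: str | None = None,
) -> MAReport:
    """MA between two methods, with transmitted/non-transmitted splits.

    Agreement per sample x locus is the size of the multiset intersection
    of the two unordered pairs after reduction (0, 1 or 2).  Only samples
    typed by both methods at every evaluated locus enter the denominator;
    others are excluded and listed.  MA_T / MA_NT restrict numerator and
    denominator to the slot class given by trio phasing under
    ``phase_reference`` (default ``method_a``): child slots count as
    transmitted, phased parent slots by their class, unresolved slots are
    excluded from both and counted separately.
    """
    if method_a == method_b:
        raise ValueError("method_a and method_b must differ")
    phase_reference = phase_reference or method_a

    def fully_typed(sample_id: str, method: str) -> bool:
        return all(cohort.get_call(method, sample_id, l) is not None for l in cohort.loci)

    included: list[SampleRecord] = []
    excluded: list[str] = []
    for rec in cohort.samples:
        if fully_typed(rec.sample_id, method_a) and fully_typed(rec.sample_id, method_b):
            included.append(rec)
        else:
            excluded.append(rec.sample_id)
    if not included:
        raise ValueError(
            f"no sample typed by both {method_a!r} and {method_b!r} at all loci"
        )

    # phase parents of complete families under the reference method
    phases: dict[str, TransmissionPhase] = {}
    for fam_id, members in cohort.complete_families().items():
        if all(
            fully_typed(members[r].sample_id, phase_reference)
            for r in ("child", "mother", "father")
        ):
            phases[fam_id] = classify_transmission(
                cohort, fam_id, phase_reference, resolution, ignore_suffix
            )

    n_agree = 0
    per_individual: dict[str, int] = {}
    agree_per_locus: Counter = Counter()
    slot_counts = {"transmitted": Counter(), "non_transmitted": Counter(), "unresolved": Counter()}
    slot_agree = {"transmitted": Counter(), "non_transmitted": Counter()}
    for rec in included:
        total = 0
        phase = phases.get(rec.family_id)
        for locus in cohort.loci:
            pair_a = cohort.get_call(method_a, rec.sample_id, locus).alleles
            pair_b = cohort.get_call(method_b, rec.sample_id, locus).alleles
            agree = _slot_agreement(pair_a, pair_b, resolution, ignore_suffix)
            total += sum(agree)
            agree_per_locus[locus] += sum(agree)
            for slot in (0, 1):
                if rec.role == "child":
                    cls = "transmitted"
                elif phase is not None:
                    cls = phase.slot_class(rec.sample_id, locus, slot)
                else:
                    cls = "unresolved"
                slot_counts[cls][locus] += 1
                if cls != "unresolved" and agree[slot]:
                    slot_agree[cls][locus] += 1
        per_individual[rec.sample_id] = total
        n_agree += total

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    n_pop = len(included)
    loci = list(cohort.loci)
    denom = n_pop * 2 * len(loci)
    sum_t = sum(slot_counts["transmitted"].values())
    sum_nt = sum(slot_counts["non_transmitted"].values())
    return MAReport(
        methods=(method_a, method_b),
        resolution=resolution,
        n_population=n_pop,
        loci=loci,
        n_agree=n_agree,
        ma_total=n_agree / denom,
        ma_t=ratio(sum(slot_agree["transmitted"].values()), sum_t),
        ma_nt=ratio(sum(slot_agree["non_transmitted"].values()), sum_nt),
        ma_per_locus={l: agree_per_locus[l] / (2 * n_pop) for l in loci},
        ma_t_per_locus={
            l: ratio(slot_agree["transmitted"][l], slot_counts["transmitted"][l]) for l in loci
        },
        ma_nt_per_locus={
            l: ratio(slot_agree["non_transmitted"][l], slot_counts["non_transmitted"][l])
            for l in loci
        },
        per_individual_agree=per_individual,
        n_slots_t=sum_t,
        n_slots_nt=sum_nt,
        n_slots_unresolved=sum(slot_counts["unresolved"].values()),
        excluded_samples=excluded,
    )
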