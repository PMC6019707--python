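"""Population statistics on typed cohorts.

Homozygosity rate (HR) per locus is the fraction of individuals carrying
two identical alleles, HR = N_hom / N_population, evaluated on the parents
by default: parental alleles are representative of the population, while a
child's alleles are a subset determined by its parents.  Allele frequencies
use direct counting (each homozygote contributes two copies, divided by
2N chromosomes).  Both are computed after reduction to the working
resolution, so reducing 8-digit calls to 4 digits can merge alleles and
raise HR.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .cohort_io import CWDCatalogue, FrequencyReference, TrioCohort
from .nomenclature import AlleleName, canonical_key, format_allele, reduce_allele

__all__ = [
    "HRReport",
    "AlleleFrequencyTable",
    "FrequencyComparison",
    "CWDClassification",
    "homozygosity_rate",
    "allele_frequencies",
    "rank_top_alleles",
    "compare_to_reference",
    "classify_cwd",
    "catalogue_from_references",
]

DEFAULT_ROLES = frozenset({"father", "mother"})


@dataclass
class HRReport:
    """Homozygosity counts and rates for one method x resolution."""

    method: str
    resolution: int
    roles: frozenset[str]
    loci: list[str]
    n_homozygous: dict[str, int]
    n_population: dict[str, int]
    hr_per_locus: dict[str, float]
    hr_overall: float          # pooled counts: sum N_hom / sum N
    hr_mean_of_loci: float     # unweighted mean of per-locus rates

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "method": self.method,
                "resolution": self.resolution,
                "locus": l,
                "n_homozygous": self.n_homozygous[l],
                "n_population": self.n_population[l],
                "hr": self.hr_per_locus[l],
            }
            for l in self.loci
        ]
        rows.append(
            {
                "method": self.method,
                "resolution": self.resolution,
                "locus": "overall",
                "n_homozygous": sum(self.n_homozygous.values()),
                "n_population": sum(self.n_population.values()),
                "hr": self.hr_overall,
            }
        )
        return pd.DataFrame(
            rows,
            columns=["method", "resolution", "locus", "n_homozygous", "n_population", "hr"],
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "resolution": self.resolution,
            "roles": sorted(self.roles),
            "loci": list(self.loci),
            "n_homozygous": dict(self.n_homozygous),
            "n_population": dict(self.n_population),
            "hr_per_locus": dict(self.hr_per_locus),
            "hr_overall": self.hr_overall,
            "hr_mean_of_loci": self.hr_mean_of_loci,
        }


def homozygosity_rate(
    cohort: TrioCohort,
    method: str,
    resolution: int = 4,
    roles: Iterable[str] = DEFAULT_ROLES,
) -> HRReport:
    """HR = N_hom / N_population per locus, on the selected roles.

    An individual is homozygous at a locus iff its two alleles are equal
    after reduction to the working resolution.  The overall rate pools
    counts across loci; the unweighted per-locus mean is also reported.
    """
    roles = frozenset(roles)
    if not roles:
        raise ValueError("empty role selection")
    n_hom: Counter = Counter()
    n_pop: Counter = Counter()
    for rec in cohort.samples_by_role(roles):
        for locus in cohort.loci:
            call = cohort.get_call(method, rec.sample_id, locus)
            if call is None:
                continue
            n_pop[locus] += 1
            if call.reduced(resolution).is_homozygous:
                n_hom[locus] += 1
    loci = list(cohort.loci)
    if sum(n_pop.values()) == 0:
        raise ValueError(f"no individual with role in {sorted(roles)} typed by {method!r}")
    hr_per_locus = {
        l: (n_hom[l] / n_pop[l]) if n_pop[l] else float("nan") for l in loci
    }
    evaluable = [l for l in loci if n_pop[l]]
    return HRReport(
        method=method,
        resolution=resolution,
        roles=roles,
        loci=loci,
        n_homozygous={l: n_hom[l] for l in loci},
        n_population={l: n_pop[l] for l in loci},
        hr_per_locus=hr_per_locus,
        hr_overall=sum(n_hom.values()) / sum(n_pop.values()),
        hr_mean_of_loci=sum(hr_per_locus[l] for l in evaluable) / len(evaluable),
    )


@dataclass
class AlleleFrequencyTable:
    """Direct-counting allele frequencies per locus, with raw counts."""

    method: str
    resolution: int
    roles: frozenset[str]
    counts: dict[str, dict[AlleleName, int]]
    n_chromosomes: dict[str, int]

    @property
    def frequencies(self) -> dict[str, dict[AlleleName, float]]:
        return {
            locus: {a: c / self.n_chromosomes[locus] for a, c in counter.items()}
            for locus, counter in self.counts.items()
        }

    def to_table(self) -> pd.DataFrame:
        rows = []
        for locus in sorted(self.counts):
            total = self.n_chromosomes[locus]
            for allele in sorted(self.counts[locus], key=canonical_key):
                c = self.counts[locus][allele]
                rows.append(
                    {
                        "method": self.method,
                        "resolution": self.resolution,
                        "locus": locus,
                        "allele": format_allele(allele),
                        "count": c,
                        "n_chromosomes": total,
                        "frequency": c / total,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["method", "resolution", "locus", "allele", "count", "n_chromosomes", "frequency"],
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "resolution": self.resolution,
            "roles": sorted(self.roles),
            "frequencies": {
                locus: {format_allele(a): f for a, f in sorted(freqs.items(), key=lambda kv: canonical_key(kv[0]))}
                for locus, freqs in self.frequencies.items()
            },
            "n_chromosomes": dict(self.n_chromosomes),
        }


def allele_frequencies(
    cohort: TrioCohort,
    method: str,
    resolution: int = 4,
    roles: Iterable[str] = DEFAULT_ROLES,
) -> AlleleFrequencyTable:
    """Direct counting: allele count over 2N chromosomes per locus."""
    roles = frozenset(roles)
    if not roles:
        raise ValueError("empty role selection")
    counts: dict[str, Counter] = {}
    n_ind: Counter = Counter()
    for rec in cohort.samples_by_role(roles):
        for locus in cohort.loci:
            call = cohort.get_call(method, rec.sample_id, locus)
            if call is None:
                continue
            n_ind[locus] += 1
            locus_counts = counts.setdefault(locus, Counter())
            for allele in call.alleles:
                locus_counts[reduce_allele(allele, resolution)] += 1
    if not counts:
        raise ValueError(f"no typed individual with role in {sorted(roles)} for {method!r}")
    return AlleleFrequencyTable(
        method=method,
        resolution=resolution,
        roles=roles,
        counts={l: dict(c) for l, c in counts.items()},
        n_chromosomes={l: 2 * n_ind[l] for l in counts},
    )


@dataclass
class FrequencyComparison:
    """Top-k cohort alleles per locus, optionally aligned with references.

    ``rows`` holds, per locus, the ranked alleles with cohort frequency and
    (population -> frequency-or-None) reference columns.  Cohort alleles
    absent from every reference are listed in ``absent_everywhere``.
    """

    method: str
    k: int
    populations: list[str]
    rows: list[dict]
    absent_everywhere: list[str] = field(default_factory=list)

    def to_table(self) -> pd.DataFrame:
        cols = ["method", "locus", "rank", "allele", "cohort_frequency", *self.populations]
        return pd.DataFrame(self.rows, columns=cols)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "k": self.k,
            "populations": list(self.populations),
            "rows": list(self.rows),
            "absent_everywhere": list(self.absent_everywhere),
        }


def rank_top_alleles(freqs: AlleleFrequencyTable, k: int) -> FrequencyComparison:
    """Top-k alleles per locus by descending frequency.

    Exact frequency ties are broken by the canonical allele string, so the
    ranking is deterministic.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    rows = []
    for locus in sorted(freqs.counts):
        ranked = sorted(
            freqs.frequencies[locus].items(), key=lambda kv: (-kv[1], canonical_key(kv[0]))
        )
        for rank, (allele, f) in enumerate(ranked[:k], start=1):
            rows.append(
                {
                    "method": freqs.method,
                    "locus": locus,
                    "rank": rank,
                    "allele": format_allele(allele),
                    "cohort_frequency": f,
                }
            )
    return FrequencyComparison(method=freqs.method, k=k, populations=[], rows=rows)


def compare_to_reference(
    freqs: AlleleFrequencyTable,
    references: Sequence[FrequencyReference],
    k: int = 5,
) -> FrequencyComparison:
    """Attach each reference population's frequency (or an absent marker)
    to the cohort's top-k alleles; matching is at 4-digit resolution."""
    if not references:
        raise ValueError("empty reference list")
    comparison = rank_top_alleles(freqs, k)
    comparison.populations = [r.population for r in references]
    absent: list[str] = []
    for row in comparison.rows:
        allele = reduce_allele(
            _parse_back(row["allele"]), 4
        )
        found_any = False
        for ref in references:
            val = ref.lookup(allele)
            row[ref.population] = val
            found_any = found_any or val is not None
        if not found_any:
            absent.append(row["allele"])
    comparison.absent_everywhere = absent
    return comparison


def _parse_back(text: str) -> AlleleName:
    from .nomenclature import parse_allele

    return parse_allele(text)


@dataclass
class CWDClassification:
    """Per-allele common/rare labels and per-locus rare fractions."""

    method: str
    labels: dict[str, str]  # canonical allele string -> "common" | "rare"
    per_locus: dict[str, dict[str, int]]  # locus -> {n_common, n_rare}

    def fraction_rare(self, locus: str) -> float:
        c = self.per_locus[locus]
        total = c["n_common"] + c["n_rare"]
        return c["n_rare"] / total if total else float("nan")

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "method": self.method,
                "locus": l,
                "n_common": c["n_common"],
                "n_rare": c["n_rare"],
                "fraction_rare": self.fraction_rare(l),
            }
            for l, c in sorted(self.per_locus.items())
        ]
        return pd.DataFrame(
            rows, columns=["method", "locus", "n_common", "n_rare", "fraction_rare"]
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "labels": dict(self.labels),
            "per_locus": {l: dict(c) for l, c in self.per_locus.items()},
        }


def classify_cwd(freqs: AlleleFrequencyTable, catalogue: CWDCatalogue) -> CWDClassification:
    """Label each observed allele common/well-documented or rare.

    An allele is common iff its 4-digit reduction appears in the
    catalogue; counts are per distinct observed allele, not per carrier.
    """
    if not catalogue.entries:
        raise ValueError("empty CWD catalogue")
    labels: dict[str, str] = {}
    per_locus: dict[str, dict[str, int]] = {}
    for locus in sorted(freqs.counts):
        counts = {"n_common": 0, "n_rare": 0}
        for allele in sorted(freqs.counts[locus], key=canonical_key):
            label = "common" if allele in catalogue else "rare"
            labels[format_allele(allele)] = label
            counts["n_common" if label == "common" else "n_rare"] += 1
        per_locus[locus] = counts
    return CWDClassification(method=freqs.method, labels=labels, per_locus=per_locus)


def catalogue_from_references(
    references: Sequence[FrequencyReference],
    min_frequency: float = 0.001,
    min_sample_size: int = 1500,
) -> CWDCatalogue:
    """Build a common-allele catalogue from reference frequency tables.

    An allele qualifies when some reference population of at least
    ``min_sample_size`` individuals reports it above ``min_frequency``;
    populations without a stated sample size are skipped.
    """
    entries = set()
    for ref in references:
        if ref.sample_size is None or ref.sample_size < min_sample_size:
            continue
        for allele, freq in ref.entries.items():
            if freq > min_frequency:
                entries.add(reduce_allele(allele, 4))
    return CWDCatalogue(frozenset(entries))
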