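"""Tabular I/O for trio cohorts: pedigrees, genotype tables, tool dialects,
reference frequency tables, and CWD catalogues.

All tabular formats are plain tab-separated text read and written through
pandas.  Reader errors always carry the offending row or line number.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .nomenclature import (
    AlleleName,
    AlleleParseError,
    canonical_key,
    format_allele,
    parse_allele,
    reduce_allele,
)

__all__ = [
    "CohortIOError",
    "SampleRecord",
    "GenotypeCall",
    "TrioCohort",
    "FrequencyReference",
    "CWDCatalogue",
    "ROLES",
    "read_pedigree",
    "write_pedigree",
    "read_genotype_table",
    "write_genotype_table",
    "read_optitype_result",
    "read_polysolver_winners",
    "read_frequency_reference",
    "read_cwd_catalogue",
    "write_report",
]

logger = logging.getLogger(__name__)

ROLES = ("father", "mother", "child")


class CohortIOError(ValueError):
    """Raised on malformed cohort input files; messages carry row numbers."""


@dataclass(frozen=True)
class SampleRecord:
    """One individual: sample id, family id, and trio role."""

    sample_id: str
    family_id: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise CohortIOError(
                f"unknown role {self.role!r} for sample {self.sample_id!r}; "
                f"expected one of {ROLES}"
            )


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered pair of alleles for one sample x locus x method.

    Alleles are stored sorted by canonical string so equality and hashing
    are order-independent; homozygotes keep both copies (multiset
    semantics).
    """

    sample_id: str
    locus: str
    method: str
    alleles: tuple[AlleleName, AlleleName]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise CohortIOError(
                f"genotype for {self.sample_id}/{self.locus} must have exactly two alleles"
            )
        for a in self.alleles:
            if a.gene != self.locus:
                raise CohortIOError(
                    f"allele {format_allele(a)} does not belong to locus "
                    f"{self.locus!r} (sample {self.sample_id!r})"
                )
        object.__setattr__(
            self, "alleles", tuple(sorted(self.alleles, key=canonical_key))
        )

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    def reduced(self, resolution: int) -> "GenotypeCall":
        """The same call with both alleles reduced to ``resolution``."""
        return GenotypeCall(
            sample_id=self.sample_id,
            locus=self.locus,
            method=self.method,
            alleles=tuple(reduce_allele(a, resolution) for a in self.alleles),
        )


@dataclass
class TrioCohort:
    """Samples plus per-(method, sample, locus) genotype calls.

    Families missing any member are flagged incomplete and excluded from
    descent-accuracy evaluation; every (method, sample, locus) key appears
    at most once.
    """

    samples: list[SampleRecord] = field(default_factory=list)
    typings: dict[tuple[str, str, str], GenotypeCall] = field(default_factory=dict)
    loci: list[str] = field(default_factory=lambda: ["A", "B", "C"])

    def add_call(self, call: GenotypeCall) -> None:
        key = (call.method, call.sample_id, call.locus)
        if key in self.typings:
            raise CohortIOError(f"duplicate genotype call for {key}")
        self.typings[key] = call

    def get_call(self, method: str, sample_id: str, locus: str) -> GenotypeCall | None:
        return self.typings.get((method, sample_id, locus))

    @property
    def methods(self) -> list[str]:
        return sorted({m for m, _, _ in self.typings})

    def families(self) -> dict[str, dict[str, SampleRecord]]:
        """family_id -> {role: record}; raises on duplicate roles."""
        fams: dict[str, dict[str, SampleRecord]] = {}
        for rec in self.samples:
            slot = fams.setdefault(rec.family_id, {})
            if rec.role in slot:
                raise CohortIOError(
                    f"family {rec.family_id!r} has two {rec.role!r} members"
                )
            slot[rec.role] = rec
        return fams

    def complete_families(self) -> dict[str, dict[str, SampleRecord]]:
        return {f: m for f, m in self.families().items() if len(m) == 3}

    def incomplete_families(self) -> list[str]:
        return sorted(f for f, m in self.families().items() if len(m) < 3)

    def samples_by_role(self, roles: Iterable[str]) -> list[SampleRecord]:
        roles = set(roles)
        return [s for s in self.samples if s.role in roles]


@dataclass
class FrequencyReference:
    """Published allele frequencies for one population (4-digit keys)."""

    population: str
    entries: dict[AlleleName, float]
    sample_size: int | None = None

    def lookup(self, allele: AlleleName) -> float | None:
        return self.entries.get(reduce_allele(allele, 4))


@dataclass
class CWDCatalogue:
    """Set of Common-and-Well-Documented alleles at 4-digit resolution."""

    entries: frozenset[AlleleName]

    def __contains__(self, allele: AlleleName) -> bool:
        return reduce_allele(allele, 4) in self.entries


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CohortIOError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortIOError(f"{path}: missing required column(s) {missing}")
    return df


def read_pedigree(path: str | Path) -> list[SampleRecord]:
    """Read a pedigree TSV (sample_id, family_id, role) and validate it.

    Duplicate sample ids or two same-role members in a family are errors;
    families missing a member are logged as incomplete (the cohort flags
    them, they are not errors here).
    """
    df = _read_tsv(path, ["sample_id", "family_id", "role"])
    records: list[SampleRecord] = []
    seen: set[str] = set()
    by_family: dict[str, set[str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row.sample_id)
        if sid in seen:
            raise CohortIOError(f"{path} row {i}: duplicate sample_id {sid!r}")
        seen.add(sid)
        try:
            rec = SampleRecord(sid, str(row.family_id), str(row.role))
        except CohortIOError as exc:
            raise CohortIOError(f"{path} row {i}: {exc}") from None
        roles = by_family.setdefault(rec.family_id, set())
        if rec.role in roles:
            raise CohortIOError(
                f"{path} row {i}: family {rec.family_id!r} already has a {rec.role!r}"
            )
        roles.add(rec.role)
        records.append(rec)
    for fam, roles in sorted(by_family.items()):
        if len(roles) < 3:
            logger.warning(
                "family %s is incomplete (missing %s); excluded from trio analyses",
                fam,
                sorted(set(ROLES) - roles),
            )
    return records


def write_pedigree(samples: Iterable[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.family_id, s.role) for s in samples],
        columns=["sample_id", "family_id", "role"],
    ).to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str | Path, method_label: str) -> list[GenotypeCall]:
    """Read the generic genotype TSV (sample_id, locus, allele1, allele2)."""
    df = _read_tsv(path, ["sample_id", "locus", "allele1", "allele2"])
    calls: list[GenotypeCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            a1 = parse_allele(str(row.allele1), dialect="colon")
            a2 = parse_allele(str(row.allele2), dialect="colon")
            calls.append(
                GenotypeCall(str(row.sample_id), str(row.locus), method_label, (a1, a2))
            )
        except (AlleleParseError, CohortIOError) as exc:
            raise CohortIOError(f"{path} row {i}: {exc}") from None
    return calls


def write_genotype_table(calls: Iterable[GenotypeCall], path: str | Path) -> None:
    rows = [
        (c.sample_id, c.locus, format_allele(c.alleles[0]), format_allele(c.alleles[1]))
        for c in calls
    ]
    pd.DataFrame(rows, columns=["sample_id", "locus", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )


OPTITYPE_COLUMNS = ("A1", "A2", "B1", "B2", "C1", "C2")


def read_optitype_result(path: str | Path, sample_id: str) -> list[GenotypeCall]:
    """Read one Optitype result table row into A/B/C calls.

    Optitype emits a TSV with columns A1,A2,B1,B2,C1,C2 (4-digit colon
    identifiers without the ``HLA-`` prefix) plus score columns.
    """
    df = _read_tsv(path, OPTITYPE_COLUMNS)
    if len(df) == 0:
        raise CohortIOError(f"{path}: empty Optitype result")
    row = df.iloc[0]
    calls = []
    for locus in ("A", "B", "C"):
        pair = []
        for col in (f"{locus}1", f"{locus}2"):
            cell = row[col]
            if pd.isna(cell) or str(cell).strip() == "":
                raise CohortIOError(f"{path}: empty allele cell {col!r}")
            try:
                pair.append(parse_allele(str(cell), dialect="colon"))
            except AlleleParseError as exc:
                raise CohortIOError(f"{path} cell {col!r}: {exc}") from None
        calls.append(GenotypeCall(sample_id, locus, "optitype", tuple(pair)))
    return calls


def read_polysolver_winners(path: str | Path, sample_id: str) -> list[GenotypeCall]:
    """Read a Polysolver winners file (one ``HLA-X<TAB>tok<TAB>tok`` line
    per class I locus) into calls at native (up to 8-digit) resolution."""
    path = Path(path)
    try:
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    except OSError as exc:
        raise CohortIOError(f"cannot read {path}: {exc}") from exc
    if len(lines) != 3:
        raise CohortIOError(
            f"{path}: expected 3 winner lines (loci A, B, C), found {len(lines)}"
        )
    calls = []
    for i, line in enumerate(lines, start=1):
        parts = line.split()
        if len(parts) != 3:
            raise CohortIOError(
                f"{path} line {i}: expected 'HLA-X allele1 allele2', got {line!r}"
            )
        locus = parts[0].upper().removeprefix("HLA-")
        try:
            pair = tuple(parse_allele(tok, dialect="underscore") for tok in parts[1:])
            calls.append(GenotypeCall(sample_id, locus, "polysolver", pair))
        except (AlleleParseError, CohortIOError) as exc:
            raise CohortIOError(f"{path} line {i}: {exc}") from None
    return calls


def read_frequency_reference(path: str | Path) -> list[FrequencyReference]:
    """Read a frequency TSV (population, allele, frequency[, sample_size]).

    Alleles are stored reduced to 4-digit resolution; frequencies outside
    [0, 1] are errors.  Partial tables are allowed, but a per-locus sum
    above 1 (plus tolerance) is an error.
    """
    df = _read_tsv(path, ["population", "allele", "frequency"])
    refs: dict[str, FrequencyReference] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            allele = reduce_allele(parse_allele(str(row.allele)), 4)
        except AlleleParseError as exc:
            raise CohortIOError(f"{path} row {i}: {exc}") from None
        try:
            freq = float(row.frequency)
        except ValueError:
            raise CohortIOError(
                f"{path} row {i}: non-numeric frequency {row.frequency!r}"
            ) from None
        if not 0.0 <= freq <= 1.0:
            raise CohortIOError(f"{path} row {i}: frequency {freq} outside [0, 1]")
        size = None
        if "sample_size" in df.columns and not pd.isna(getattr(row, "sample_size")):
            size = int(float(getattr(row, "sample_size")))
        pop = str(row.population)
        if pop not in refs:
            refs[pop] = FrequencyReference(pop, {}, size)
        refs[pop].entries[allele] = freq
        if size is not None:
            refs[pop].sample_size = size
    for ref in refs.values():
        sums = Counter()
        for allele, freq in ref.entries.items():
            sums[allele.gene] += freq
        for locus, total in sums.items():
            if total > 1.0 + 1e-6:
                raise CohortIOError(
                    f"{path}: population {ref.population!r} locus {locus} "
                    f"frequencies sum to {total:.4f} > 1"
                )
    return list(refs.values())


def read_cwd_catalogue(path: str | Path) -> CWDCatalogue:
    """Read a CWD catalogue TSV (single ``allele`` column, colon dialect)."""
    df = _read_tsv(path, ["allele"])
    entries = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            entries.add(reduce_allele(parse_allele(str(row.allele)), 4))
        except AlleleParseError as exc:
            raise CohortIOError(f"{path} row {i}: {exc}") from None
    return CWDCatalogue(frozenset(entries))


# ---------------------------------------------------------------------------
# report output


def write_report(report, path: str | Path, format: str = "tsv") -> None:
    """Serialize any evaluation report (an object exposing ``to_table()``
    and ``to_dict()``) with deterministic column order."""
    path = Path(path)
    if format == "tsv":
        table = report.to_table()
        table.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}; expected tsv or json")


def cohort_from_files(
    pedigree_path: str | Path,
    genotype_paths: Mapping[str, str | Path],
    loci: Iterable[str] = ("A", "B", "C"),
) -> TrioCohort:
    """Assemble a cohort from a pedigree TSV and per-method genotype TSVs."""
    cohort = TrioCohort(samples=read_pedigree(pedigree_path), loci=list(loci))
    for method, path in genotype_paths.items():
        for call in read_genotype_table(path, method):
            cohort.add_call(call)
    return cohort
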