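"""HLA allele nomenclature: parsing, formatting, reduction, and comparison.

HLA alleles are named by the WHO Nomenclature Committee as a gene symbol
followed by up to four colon-separated numeric fields, e.g.
``HLA-A*02:01:01:02``.  The number of fields determines the *resolution*:

* 2-digit (one field): serological allele group, e.g. ``A*02``
* 4-digit (two fields): distinct protein, e.g. ``A*02:01``
* 6-digit (three fields): synonymous coding variants
* 8-digit (four fields): non-coding (intron/UTR) variants

An optional trailing letter (``L``, ``N``, ``S``, ``Q``, ``C``, ``A``)
flags expression status; it is parsed and retained but ignored in
comparisons by default.  ``G``/``P`` ambiguity-group designators are out of
scope and rejected.

Two textual dialects are supported: the standard colon dialect
(``A*02:01``, optionally prefixed ``HLA-``) and the underscore dialect used
by Polysolver-style outputs (``hla_a_02_01``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AlleleName",
    "AlleleParseError",
    "VALID_RESOLUTIONS",
    "parse_allele",
    "format_allele",
    "resolution_of",
    "reduce_allele",
    "alleles_equal_at",
    "serotype_group",
    "canonical_key",
]

#: Valid resolution levels, in digits (2 x number of fields).
VALID_RESOLUTIONS = (2, 4, 6, 8)

#: Expression-status suffix letters admitted by the nomenclature.
EXPRESSION_SUFFIXES = frozenset("LNSQCA")

#: Group designators (ambiguity groups) that we deliberately do not model.
_GROUP_DESIGNATORS = frozenset("GP")


class AlleleParseError(ValueError):
    """Raised when an allele identifier cannot be parsed."""


@dataclass(frozen=True)
class AlleleName:
    """A structured HLA allele identifier.

    Parameters
    ----------
    gene
        Locus symbol, e.g. ``"A"``, ``"B"``, ``"C"`` (free text for other
        loci).
    fields
        One to four numeric fields of 2-4 digit characters each; leading
        zeros are significant and preserved.
    suffix
        Optional single-letter expression flag (``L``, ``N``, ...).
    """

    gene: str
    fields: tuple[str, ...]
    suffix: str | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise AlleleParseError("allele has an empty gene symbol")
        if not isinstance(self.fields, tuple):
            object.__setattr__(self, "fields", tuple(self.fields))
        if not 1 <= len(self.fields) <= 4:
            raise AlleleParseError(
                f"allele {self.gene!r} has {len(self.fields)} fields; expected 1-4"
            )
        for f in self.fields:
            if not (f.isdigit() and 2 <= len(f) <= 4):
                raise AlleleParseError(
                    f"invalid allele field {f!r}: expected 2-4 digit characters"
                )
        if self.suffix is not None and self.suffix not in EXPRESSION_SUFFIXES:
            raise AlleleParseError(
                f"invalid expression suffix {self.suffix!r}; "
                f"expected one of {sorted(EXPRESSION_SUFFIXES)}"
            )

    @property
    def resolution(self) -> int:
        """Resolution in digits: 2 x number of fields."""
        return 2 * len(self.fields)

    def __str__(self) -> str:
        return format_allele(self)


def canonical_key(a: AlleleName) -> tuple[str, tuple[str, ...], str]:
    """Deterministic sort key: gene, then fields, then suffix (empty last)."""
    return (a.gene, a.fields, a.suffix or "")


def _extract_suffix(last_field: str, token: str) -> tuple[str, str | None]:
    """Split a trailing letter off the last numeric field, if present."""
    if last_field and last_field[-1].isalpha():
        letter = last_field[-1].upper()
        if letter in _GROUP_DESIGNATORS:
            raise AlleleParseError(
                f"{token!r} carries the {letter!r} group designator; "
                "G/P ambiguity groups are not supported"
            )
        if letter not in EXPRESSION_SUFFIXES:
            raise AlleleParseError(
                f"unrecognised suffix letter {letter!r} in token {token!r}"
            )
        return last_field[:-1], letter
    return last_field, None


def _check_fields(fields: list[str], text: str) -> None:
    if not fields or any(f == "" for f in fields):
        raise AlleleParseError(f"empty allele field in {text!r}")
    if len(fields) > 4:
        raise AlleleParseError(f"{text!r} has {len(fields)} fields; at most 4 allowed")
    for f in fields:
        if not f.isdigit():
            raise AlleleParseError(f"non-digit allele field {f!r} in {text!r}")


def parse_allele(text: str, dialect: str | None = None) -> AlleleName:
    """Parse an allele identifier in either dialect.

    When ``dialect`` is ``None`` it is auto-detected: a leading ``hla_`` or
    the absence of ``*`` selects the underscore dialect, otherwise colon.
    A ``HLA-`` prefix, surrounding whitespace, and a space before the
    expression suffix (as in ``HLA-A*02:01:01:02 L``) are accepted.
    """
    if not text or not text.strip():
        raise AlleleParseError("empty allele identifier")
    raw = text
    text = "".join(text.split())  # tolerate internal whitespace, e.g. "...02 L"

    if dialect is None:
        dialect = "underscore" if text.lower().startswith("hla_") or "*" not in text else "colon"
    if dialect not in ("colon", "underscore"):
        raise ValueError(f"unknown dialect {dialect!r}")

    if dialect == "colon":
        body = text
        if body.upper().startswith("HLA-"):
            body = body[4:]
        if "*" not in body:
            raise AlleleParseError(f"missing '*' gene separator in {raw!r}")
        gene, _, rest = body.partition("*")
        if not gene:
            raise AlleleParseError(f"empty gene symbol in {raw!r}")
        fields = rest.split(":")
    else:
        tokens = text.lower().split("_")
        if tokens and tokens[0] == "hla":
            tokens = tokens[1:]
        if len(tokens) < 2:
            raise AlleleParseError(f"underscore identifier {raw!r} has no allele fields")
        gene, fields = tokens[0].upper(), tokens[1:]

    if not fields or fields == [""]:
        raise AlleleParseError(f"{raw!r} has no allele fields")
    fields = list(fields)
    fields[-1], suffix = _extract_suffix(fields[-1], raw)
    _check_fields(fields, raw)
    try:
        return AlleleName(gene=gene, fields=tuple(fields), suffix=suffix)
    except AlleleParseError as exc:
        raise AlleleParseError(f"cannot parse {raw!r}: {exc}") from None


def format_allele(a: AlleleName, dialect: str = "colon", with_prefix: bool = False) -> str:
    """Serialize an allele name; inverse of :func:`parse_allele`."""
    if dialect == "colon":
        out = f"{a.gene}*{':'.join(a.fields)}{a.suffix or ''}"
        return f"HLA-{out}" if with_prefix else out
    if dialect == "underscore":
        out = "_".join(["hla", a.gene.lower(), *a.fields]) + (a.suffix or "").lower()
        return out
    raise ValueError(f"unknown dialect {dialect!r}")


def resolution_of(a: AlleleName) -> int:
    """Resolution in digits (2, 4, 6 or 8)."""
    return a.resolution


def reduce_allele(a: AlleleName, target_resolution: int) -> AlleleName:
    """Truncate an allele to a coarser resolution.

    Keeps only the first ``target_resolution / 2`` fields and drops the
    expression suffix when truncation occurs; an allele already at or below
    the target is returned unchanged (no padding).  E.g.
    ``A*02:01:01:02`` at 4 digits becomes ``A*02:01``.
    """
    if target_resolution not in VALID_RESOLUTIONS:
        raise ValueError(
            f"invalid target resolution {target_resolution!r}; expected one of {VALID_RESOLUTIONS}"
        )
    if a.resolution <= target_resolution:
        return a
    return AlleleName(gene=a.gene, fields=a.fields[: target_resolution // 2], suffix=None)


def alleles_equal_at(
    a: AlleleName,
    b: AlleleName,
    resolution: int = 4,
    ignore_suffix: bool = True,
) -> bool:
    """Equality after reduction to a common resolution.

    Gene symbols must match and the reduced field tuples must be identical.
    Expression suffixes are ignored by default.
    """
    if a.gene != b.gene:
        return False
    ra, rb = reduce_allele(a, resolution), reduce_allele(b, resolution)
    if ra.fields != rb.fields:
        return False
    return ignore_suffix or ra.suffix == rb.suffix


def serotype_group(a: AlleleName) -> AlleleName:
    """The 2-digit serological allele group of an allele."""
    return reduce_allele(a, 2)
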