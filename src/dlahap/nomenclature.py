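"""DLA allele and haplotype nomenclature.

Canine MHC (DLA) alleles are named like their HLA counterparts: a locus
token (``88``, ``12``, ``88L`` or ``DRB1``), an asterisk, and one to four
colon-separated numeric fields, e.g. ``DLA-88*004:02`` or
``DRB1*092:01:1``.  The first field (field-1) groups alleles whose
peptide-binding regions are similar; truncating names to field-1 is how
breed-level haplotype frequencies are coarsened before multivariate
analyses.  Alleles awaiting an official name carry a tentative ``nov##``
token instead of numeric fields.

DLA-12 and DLA-88L occupy the same chromosomal slot: a haplotype carries
either a DLA-12 allele (structure ``88-12-DRB1``) or a DLA-88L allele
(structure ``88-88L-DRB1``).  Officially DLA-88L alleles are named with
the ``DLA-88*`` prefix, so the sublocus cannot be recovered from the
name alone; here it is carried as an explicit locus tag and preserved by
the canonical text format, while :meth:`AlleleName.display` renders the
official ``88*`` spelling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from functools import total_ordering
from typing import Iterator

__all__ = [
    "AlleleName",
    "HaplotypeLabel",
    "AlleleParseError",
    "InvalidHaplotypeError",
    "STRUCTURE_12",
    "STRUCTURE_88L",
    "parse_allele",
    "parse_haplotype",
    "collapse_field1",
    "haplotype_structure",
]

LOCI = ("88", "12", "88L", "DRB1")
_LOCUS_RANK = {"88": 0, "12": 1, "88L": 2, "DRB1": 3}

STRUCTURE_12 = "88-12-DRB1"
STRUCTURE_88L = "88-88L-DRB1"

# Longest alternatives first so "88L" is not consumed as "88".
_ALLELE_RE = re.compile(r"^(?:DLA-)?(88L|DRB1|88|12)\*(\d+(?::\d+)*|nov\d+)$")


class AlleleParseError(ValueError):
    """Raised when an allele or haplotype label does not match the grammar."""


class InvalidHaplotypeError(ValueError):
    """Raised when three alleles cannot form an 88-12/88L-DRB1 haplotype."""


@total_ordering
@dataclass(frozen=True)
class AlleleName:
    """A parsed DLA allele name.

    Parameters
    ----------
    locus
        One of ``"88"``, ``"12"``, ``"88L"``, ``"DRB1"``.  ``"88L"`` is a
        sublocus tag: such alleles are officially spelled ``88*...``.
    fields
        Colon-separated name fields.  For a tentative allele this is the
        single ``nov##`` token.
    tentative
        True for provisional ``nov##`` names that have no official field
        structure yet.
    """

    locus: str
    fields: tuple[str, ...]
    tentative: bool = False

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise AlleleParseError(f"unknown locus {self.locus!r}")
        if not self.fields:
            raise AlleleParseError("allele must carry at least one field")
        if self.tentative:
            if len(self.fields) != 1 or not re.fullmatch(r"nov\d+", self.fields[0]):
                raise AlleleParseError(
                    f"tentative allele must carry a single 'nov##' token, got {self.fields!r}"
                )
        else:
            if len(self.fields) > 4:
                raise AlleleParseError(f"more than four name fields in {self.fields!r}")
            for f in self.fields:
                if not f.isdigit():
                    raise AlleleParseError(f"non-numeric name field {f!r}")

    # -- formatting ---------------------------------------------------

    def format(self, dla_prefix: bool = False) -> str:
        """Canonical text form; preserves the ``88L`` sublocus tag."""
        prefix = "DLA-" if dla_prefix else ""
        return f"{prefix}{self.locus}*{':'.join(self.fields)}"

    def display(self, dla_prefix: bool = False) -> str:
        """Official spelling: DLA-88L alleles print with the ``88*`` prefix."""
        locus = "88" if self.locus == "88L" else self.locus
        prefix = "DLA-" if dla_prefix else ""
        return f"{prefix}{locus}*{':'.join(self.fields)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()

    # -- derived properties -------------------------------------------

    @property
    def field1(self) -> str:
        return self.fields[0]

    @property
    def sublocus_12_88L(self) -> bool:
        return self.locus in ("12", "88L")

    def collapse_field1(self) -> "AlleleName":
        """Truncate to the first name field; tentative names are atomic."""
        if self.tentative or len(self.fields) == 1:
            return self
        return replace(self, fields=(self.fields[0],))

    # -- ordering ------------------------------------------------------

    @property
    def sort_key(self) -> tuple:
        """Strict total order: locus, numeric alleles by field values,
        tentative alleles last within their locus (by nov number)."""
        if self.tentative:
            return (_LOCUS_RANK[self.locus], 1, (int(self.fields[0][3:]),))
        return (_LOCUS_RANK[self.locus], 0, tuple(int(f) for f in self.fields))

    def __lt__(self, other: "AlleleName") -> bool:
        if not isinstance(other, AlleleName):
            return NotImplemented
        return self.sort_key < other.sort_key


def parse_allele(label: str, locus_hint: str | None = None) -> AlleleName:
    """Parse an allele label such as ``"88*004:02"`` or ``"DLA-12*nov18"``.

    Parameters
    ----------
    label
        Text in the grammar ``[DLA-]?(88|12|88L|DRB1)*(d+(:d+)* | nov##)``.
    locus_hint
        Optional expected locus; a mismatch raises
        :class:`AlleleParseError`.  Because DLA-88L alleles are officially
        spelled ``88*...``, a hint of ``"88L"`` reinterprets an ``88``-
        prefixed label as sublocus 88L.
    """
    if not isinstance(label, str):
        raise AlleleParseError(f"allele label must be text, got {type(label).__name__}")
    m = _ALLELE_RE.match(label.strip())
    if m is None:
        raise AlleleParseError(f"malformed allele label {label.strip()!r}")
    locus, body = m.group(1), m.group(2)
    if locus_hint is not None:
        if locus_hint == "88L" and locus == "88":
            locus = "88L"
        elif locus != locus_hint:
            raise AlleleParseError(
                f"allele {label!r}: locus {locus!r} does not match expected {locus_hint!r}"
            )
    tentative = body.startswith("nov")
    fields = (body,) if tentative else tuple(body.split(":"))
    return AlleleName(locus=locus, fields=fields, tentative=tentative)


def collapse_field1(a: AlleleName) -> AlleleName:
    """Functional form of :meth:`AlleleName.collapse_field1`."""
    return a.collapse_field1()


@total_ordering
@dataclass(frozen=True)
class HaplotypeLabel:
    """An ordered 88-12/88L-DRB1 allele triple on one chromosome."""

    a88: AlleleName
    a12_88L: AlleleName
    drb1: AlleleName

    def __post_init__(self) -> None:
        if self.a88.locus != "88":
            raise InvalidHaplotypeError(f"first slot must be DLA-88, got {self.a88}")
        if self.a12_88L.locus not in ("12", "88L"):
            raise InvalidHaplotypeError(
                f"middle slot must be DLA-12 or DLA-88L, got {self.a12_88L}"
            )
        if self.drb1.locus != "DRB1":
            raise InvalidHaplotypeError(f"third slot must be DLA-DRB1, got {self.drb1}")

    @property
    def alleles(self) -> tuple[AlleleName, AlleleName, AlleleName]:
        return (self.a88, self.a12_88L, self.drb1)

    @property
    def structure(self) -> str:
        """``88-12-DRB1`` or ``88-88L-DRB1``, from the middle sublocus tag."""
        return STRUCTURE_12 if self.a12_88L.locus == "12" else STRUCTURE_88L

    @property
    def level(self) -> str:
        """``"field1"`` if every allele is at field-1 resolution else ``"full"``."""
        if all(a.tentative or len(a.fields) == 1 for a in self.alleles):
            return "field1"
        return "full"

    def collapse_field1(self) -> "HaplotypeLabel":
        return HaplotypeLabel(*(a.collapse_field1() for a in self.alleles))

    def label(self) -> str:
        """Canonical pipe-joined text, e.g. ``88*004:02|12*001:01:01|DRB1*006:01``."""
        return "|".join(a.format() for a in self.alleles)

    def display(self) -> str:
        """Official spelling joined with dashes (88L printed as ``88*``)."""
        return "-".join(a.display() for a in self.alleles)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label()

    @property
    def sort_key(self) -> tuple:
        return tuple(a.sort_key for a in self.alleles)

    def __lt__(self, other: "HaplotypeLabel") -> bool:
        if not isinstance(other, HaplotypeLabel):
            return NotImplemented
        return self.sort_key < other.sort_key

    def __iter__(self) -> Iterator[AlleleName]:
        return iter(self.alleles)


def parse_haplotype(label: str) -> HaplotypeLabel:
    """Parse a canonical pipe-joined haplotype label."""
    parts = label.strip().split("|")
    if len(parts) != 3:
        raise AlleleParseError(f"haplotype label needs three '|'-joined alleles: {label!r}")
    return HaplotypeLabel(
        parse_allele(parts[0], locus_hint="88"),
        parse_allele(parts[1]),
        parse_allele(parts[2], locus_hint="DRB1"),
    )


def haplotype_structure(h: HaplotypeLabel) -> str:
    """Structure tag of a haplotype (``88-12-DRB1`` vs ``88-88L-DRB1``)."""
    return h.structure
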