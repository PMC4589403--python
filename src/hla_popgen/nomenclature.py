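"""Parsing and two-field reduction of HLA allele names.

High-resolution registry typing reports alleles in WHO nomenclature, e.g.
``A*01:01:01:01``: the locus, then colon-separated numeric fields (allele
group, protein, synonymous coding, non-coding) and an optional expression
suffix (N/L/Q/S).  All downstream counting in this package is done at
two-field ("protein") resolution, so names are reduced by dropping the third
field onward.  A small exception list protects alleles that differ
non-synonymously *outside* the routinely typed exons from being collapsed
onto a two-field prefix they do not actually share protein identity with
(the shipped default contains A*02:253, which is distinguished from A*02:03
only by exon 4).
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

LOCI: tuple[str, ...] = ("A", "C", "B", "DRB1", "DQB1")

_EXPRESSION_SUFFIXES = frozenset("NLQS")

_ALLELE_RE = re.compile(
    r"^(?P<locus>[A-Z0-9]+)\*(?P<fields>\d+(?::\d+)*)(?P<suffix>[NLQS]?)$"
)


class AlleleParseError(ValueError):
    """Raised for malformed, unknown-locus, or locus-mismatched allele names."""


@functools.total_ordering
@dataclass(frozen=True)
class AlleleName:
    """A locus-qualified HLA allele name.

    Equality and hashing consider locus, the first two numeric fields and the
    expression suffix only: two names that differ just in synonymous or
    non-coding fields compare equal, which is exactly the merging convention
    of two-field typing.
    """

    locus: str
    field1: int
    field2: int
    extra_fields: tuple[int, ...] = ()
    suffix: str = ""
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise AlleleParseError(f"unknown HLA locus {self.locus!r}")
        if self.field1 <= 0 or self.field2 <= 0:
            raise AlleleParseError(f"allele fields must be positive: {self!r}")
        if self.suffix and self.suffix not in _EXPRESSION_SUFFIXES:
            raise AlleleParseError(f"unknown expression suffix {self.suffix!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleName):
            return NotImplemented
        return (self.locus, self.field1, self.field2, self.suffix) == (
            other.locus,
            other.field1,
            other.field2,
            other.suffix,
        )

    def __hash__(self) -> int:
        return hash((self.locus, self.field1, self.field2, self.suffix))

    def __lt__(self, other: "AlleleName") -> bool:
        return (self.locus, self.field1, self.field2, self.suffix) < (
            other.locus,
            other.field1,
            other.field2,
            other.suffix,
        )

    def render(self, full: bool = False) -> str:
        """Canonical text form, zero-padded to two digits per field.

        With ``full=True`` the synonymous/non-coding fields are kept; the
        default renders the two-field form used throughout the analyses.
        """
        parts = [f"{self.field1:02d}", f"{self.field2:02d}"]
        if full:
            parts += [f"{f:02d}" for f in self.extra_fields]
        return f"{self.locus}*{':'.join(parts)}{self.suffix}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_allele(text: str, expected_locus: Optional[str] = None) -> AlleleName:
    """Parse an allele string such as ``"DRB1*14:54"`` into an :class:`AlleleName`.

    Raises :class:`AlleleParseError` on malformed input, an unknown locus, or
    (when ``expected_locus`` is given) a locus mismatch.
    """
    if not text or not text.strip():
        raise AlleleParseError("empty allele name")
    text = text.strip()
    m = _ALLELE_RE.match(text)
    if m is None:
        raise AlleleParseError(f"malformed allele name {text!r}")
    locus = m.group("locus")
    if locus not in LOCI:
        raise AlleleParseError(f"unknown HLA locus {locus!r} in {text!r}")
    if expected_locus is not None and locus != expected_locus:
        raise AlleleParseError(
            f"allele {text!r} has locus {locus}, expected {expected_locus}"
        )
    fields = [int(f) for f in m.group("fields").split(":")]
    if len(fields) < 2:
        raise AlleleParseError(
            f"allele name {text!r} lacks a protein field (need at least two fields)"
        )
    return AlleleName(
        locus=locus,
        field1=fields[0],
        field2=fields[1],
        extra_fields=tuple(fields[2:]),
        suffix=m.group("suffix"),
        raw=text,
    )


@dataclass(frozen=True)
class MergeExceptionList:
    """Full-resolution names excluded from two-field merging.

    Each entry maps a full allele name to the label it must keep.  Entries are
    keyed by the canonical full rendering of the name.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.entries:
            a = parse_allele(name)
            del a  # validation only

    def lookup(self, a: AlleleName) -> Optional[str]:
        return self.entries.get(a.render(full=True))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MergeExceptionList":
        return cls(entries={parse_allele(k).render(full=True): v for k, v in pairs})

    @classmethod
    def from_file(cls, path: str | Path) -> "MergeExceptionList":
        pairs = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, label = line.partition("\t")
            pairs.append((name.strip(), label.strip() or name.strip()))
        return cls.from_pairs(pairs)


def default_exceptions() -> MergeExceptionList:
    """The bundled exception list (editable text resource in the package data)."""
    with resources.as_file(
        resources.files("hla_popgen.data") / "merge_exceptions.tsv"
    ) as p:
        return MergeExceptionList.from_file(p)


def reduce_to_two_field(
    a: AlleleName, exceptions: Optional[MergeExceptionList] = None
) -> AlleleName:
    """Collapse an allele to its two-field form, honouring the exception list.

    Synonymous/non-coding fields are dropped and the expression suffix is
    preserved (null alleles stay distinct).  Idempotent: reducing a reduced
    name returns it unchanged.
    """
    if exceptions is not None:
        label = exceptions.lookup(a)
        if label is not None:
            kept = parse_allele(label, expected_locus=a.locus)
            return AlleleName(
                kept.locus, kept.field1, kept.field2, (), kept.suffix, raw=a.raw
            )
    return AlleleName(a.locus, a.field1, a.field2, (), a.suffix, raw=a.raw)
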