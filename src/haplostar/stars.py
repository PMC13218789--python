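"""Star-allele assignment: exact matching of haplotypes to the reference.

A haplotype is assigned a star allele iff its allele vector equals a
definition-table row site-for-site.  Haplotypes absent from the table are
reported as NO_CALL (rendered ``*?``) rather than silently defaulted to
*1 — an unmatched vector is evidence of an allele the panel cannot name,
not of normal function.  When several star alleles share one defining
vector (an ambiguity group the panel cannot resolve), all names are
reported joined with ``|``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .io import AlleleDefinitionTable
from .phasing import Haplotype, PhasedPair

NO_CALL_LABEL = "*?"
FLAG_NO_CALL = "no_call"
FLAG_AMBIGUOUS = "ambiguous_star"


@dataclass(frozen=True)
class StarMatch:
    """The star alleles whose defining vector equals one haplotype.

    ``names`` is empty for NO_CALL; more than one name marks an ambiguity
    group the panel cannot separate.
    """

    names: tuple[str, ...]

    @property
    def is_nocall(self) -> bool:
        return not self.names

    @property
    def ambiguous(self) -> bool:
        return len(self.names) > 1

    @property
    def label(self) -> str:
        if self.is_nocall:
            return NO_CALL_LABEL
        return "|".join(sorted(self.names, key=star_sort_key))


def star_sort_key(name: str) -> tuple:
    """Order star names by star number, then suffix ("*2" < "*4" < "*10")."""
    m = re.match(r"\*?(\d+)(.*)", name.lstrip("*"))
    if m:
        return (0, int(m.group(1)), m.group(2))
    return (1, 0, name)


def match_haplotype(h: Haplotype, table: AlleleDefinitionTable) -> StarMatch:
    """Exact site-wise match of one haplotype against every table row."""
    if len(h) != len(table.panel):
        raise ValueError(
            f"haplotype length {len(h)} does not match panel length {len(table.panel)}"
        )
    return StarMatch(names=table.by_haplotype.get(tuple(h), ()))


def call_diplotype(
    pair: PhasedPair, table: AlleleDefinitionTable
) -> tuple[StarMatch, StarMatch]:
    """Match both haplotypes of a phased pair."""
    return match_haplotype(pair.h1, table), match_haplotype(pair.h2, table)


def render_diplotype(label1: str, label2: str) -> str:
    """Render a diplotype string with the lower star number first.

    ``*1`` + ``*4`` renders ``*1/*4``, never ``*4/*1``; NO_CALL labels sort
    last.
    """
    a, b = sorted((label1, label2), key=_label_sort_key)
    return f"{a}/{b}"


def _label_sort_key(label: str) -> tuple:
    if label == NO_CALL_LABEL:
        return (2, 0, "")
    return star_sort_key(label.split("|", 1)[0])


def parse_diplotype(text: str) -> frozenset[str] | tuple[str, str]:
    """Split a rendered diplotype string back into its two labels.

    Returns the unordered pair; the copy-number suffix (``*1x2``) is kept as
    part of the label.
    """
    parts = text.split("/")
    if len(parts) != 2:
        raise ValueError(f"not a diplotype string: {text!r}")
    a, b = parts
    return (a, b) if a <= b else (b, a)
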