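"""Readers and writers for the tabular dialects of the calling pipeline.

Four CSV/TSV dialects plus the classic PHASE text interchange format:

* genotype table   — one row per sample, one column per panel variant,
  unordered allele pairs like ``C/T``;
* allele reference — one row per star allele: name, function category,
  activity value, then one allele column per panel variant *in the same
  column order as the genotype table* (this ordering contract is the
  backbone of the whole pipeline: variant IDs are opaque labels and are
  never interpreted as genomic coordinates);
* CNV table        — ``sample_id,copies``, comma or tab separated;
* report           — the per-sample diplotype/AS/phenotype output;
* PHASE dialect    — the input format of the PHASE 2.1.1 haplotype
  reconstruction program and its best-pairs output section, so that an
  external PHASE run can be substituted for the built-in phaser.

All readers accept either an open text stream or an iterable of lines.
Delimiters are auto-detected (comma vs tab) unless given explicitly.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

from .errors import FormatError, ParseError, ValidationError

#: Sentinel for a missing genotype call at one site (``None`` by value).
MISSING = None

#: Star name conventionally denoting whole-gene deletion; it has no
#: haplotype vector and contributes activity 0.
DELETION_STAR = "*5"

#: The three admissible function categories for a star allele.
VALID_FUNCTIONS = ("Normal", "Decreased", "No function")

#: Tokens recognised as a missing call by default (configurable per read).
DEFAULT_MISSING_TOKENS = frozenset({"./.", ".", "", "NA", "?/?"})


class AmbiguityWarning(UserWarning):
    """Two or more star alleles share an identical haplotype vector."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantPanel:
    """The ordered list of assayed variants; order is significant everywhere.

    Parameters
    ----------
    variant_ids
        Unique, non-empty labels in assay column order (e.g. ``1846G>A``).
    alleles_observed
        Per-variant set of allele strings seen so far (genotype file and/or
        allele reference).
    """

    variant_ids: tuple[str, ...]
    alleles_observed: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.variant_ids) != len(self.alleles_observed):
            raise ValidationError("panel ids and allele sets differ in length")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValidationError("duplicate variant IDs in panel header")
        for vid in self.variant_ids:
            if not vid:
                raise ValidationError("empty variant ID in panel header")
        for s in self.alleles_observed:
            if any(not a for a in s):
                raise ValidationError("empty allele string in panel")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def index(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)

    def union_alleles(self, other: Sequence[Iterable[str]]) -> tuple[frozenset[str], ...]:
        """Per-site union of this panel's observed alleles with `other`."""
        if len(other) != len(self):
            raise ValidationError("allele-set sequence length does not match panel")
        return tuple(
            self.alleles_observed[i] | frozenset(other[i]) for i in range(len(self))
        )


@dataclass(frozen=True)
class GenotypeRecord:
    """One sample's unordered allele pairs across the panel.

    ``calls[i]`` is either a lexicographically sorted pair of allele strings
    or :data:`MISSING`.  Pairs are canonicalized on load so that file order
    can never leak spurious phase information.
    """

    sample_id: str
    calls: tuple[tuple[str, str] | None, ...]

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("empty sample ID")

    def n_het(self) -> int:
        return sum(1 for c in self.calls if c is not None and c[0] != c[1])

    def has_missing(self) -> bool:
        return any(c is None for c in self.calls)


@dataclass(frozen=True)
class AlleleDefinition:
    """One star allele: name, function category, activity, haplotype vector."""

    star: str
    function: str
    activity: float
    haplotype: tuple[str, ...]


@dataclass(frozen=True)
class AlleleDefinitionTable:
    """Validated star-allele reference: definitions plus lookup indices."""

    panel: VariantPanel
    definitions: tuple[AlleleDefinition, ...]
    by_star: dict[str, AlleleDefinition] = field(repr=False, default_factory=dict)
    by_haplotype: dict[tuple[str, ...], tuple[str, ...]] = field(
        repr=False, default_factory=dict
    )

    @classmethod
    def build(
        cls, panel: VariantPanel, definitions: Sequence[AlleleDefinition]
    ) -> "AlleleDefinitionTable":
        by_star: dict[str, AlleleDefinition] = {}
        by_hap: dict[tuple[str, ...], list[str]] = {}
        for d in definitions:
            if d.star in by_star:
                raise ValidationError(f"duplicate star allele name {d.star!r}")
            if len(d.haplotype) != len(panel):
                raise ValidationError(
                    f"{d.star}: haplotype vector length {len(d.haplotype)} "
                    f"does not match panel length {len(panel)}"
                )
            if d.function not in VALID_FUNCTIONS:
                raise ValidationError(
                    f"{d.star}: unknown function label {d.function!r}"
                )
            if d.activity < 0:
                raise ValidationError(f"{d.star}: negative activity value")
            by_star[d.star] = d
            by_hap.setdefault(d.haplotype, []).append(d.star)
        for hap, stars in by_hap.items():
            if len(stars) > 1:
                warnings.warn(
                    "identical haplotype vectors define an ambiguity group: "
                    + ", ".join(stars),
                    AmbiguityWarning,
                    stacklevel=3,
                )
        return cls(
            panel=panel,
            definitions=tuple(definitions),
            by_star=by_star,
            by_haplotype={h: tuple(s) for h, s in by_hap.items()},
        )

    @property
    def ambiguity_groups(self) -> list[tuple[str, ...]]:
        return [stars for stars in self.by_haplotype.values() if len(stars) > 1]

    def alleles_by_site(self) -> tuple[frozenset[str], ...]:
        """Per-variant allele set appearing in any defined haplotype."""
        sets: list[set[str]] = [set() for _ in range(len(self.panel))]
        for d in self.definitions:
            for i, a in enumerate(d.haplotype):
                sets[i].add(a)
        return tuple(frozenset(s) for s in sets)

    def activity_of(self, star: str) -> float:
        if star == DELETION_STAR and star not in self.by_star:
            return 0.0
        return self.by_star[star].activity


@dataclass(frozen=True)
class CnvRecord:
    """Per-sample gene copy number; samples absent from the table default to 2."""

    sample_id: str
    copies: int

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValidationError(
                f"{self.sample_id}: copy number must be a non-negative integer"
            )


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------

def _as_lines(stream: IO[str] | Iterable[str]) -> list[str]:
    if hasattr(stream, "read"):
        text = stream.read()  # type: ignore[union-attr]
        lines = text.splitlines()
    else:
        lines = [ln.rstrip("\r\n") for ln in stream]
    return [ln for ln in lines if ln.strip() != ""]


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _rows(lines: list[str], delimiter: str | None) -> tuple[list[list[str]], str]:
    if not lines:
        return [], delimiter or ","
    delim = delimiter or _detect_delimiter(lines[0])
    return [row for row in csv.reader(lines, delimiter=delim)], delim


# ---------------------------------------------------------------------------
# Genotype table
# ---------------------------------------------------------------------------

def read_genotype_table(
    stream: IO[str] | Iterable[str],
    delimiter: str | None = None,
    pair_sep: str = "/",
    missing_tokens: frozenset[str] | set[str] = DEFAULT_MISSING_TOKENS,
) -> tuple[VariantPanel, list[GenotypeRecord]]:
    """Parse a genotype table into a panel and one record per sample.

    The first row is a header: a sample-ID column followed by one column per
    variant; the header order defines the panel order.  Cells hold unordered
    pairs ``A{pair_sep}B`` or a missing token.  Pairs are canonicalized
    (sorted) on load.

    Raises
    ------
    ParseError
        Ragged row, or a cell that is neither a missing token nor a
        two-allele pair — the message names the 1-based file row.
    ValidationError
        Duplicate sample IDs.
    """
    lines = _as_lines(stream)
    if not lines:
        raise ParseError("empty genotype file")
    rows, _ = _rows(lines, delimiter)
    header = [c.strip() for c in rows[0]]
    if len(header) < 2:
        raise ParseError("genotype header needs an ID column and >=1 variant column")
    variant_ids = tuple(header[1:])
    n_var = len(variant_ids)

    records: list[GenotypeRecord] = []
    seen: set[str] = set()
    observed: list[set[str]] = [set() for _ in range(n_var)]
    for rownum, row in enumerate(rows[1:], start=2):
        if len(row) != n_var + 1:
            raise ParseError(
                f"row {rownum}: expected {n_var + 1} fields, found {len(row)}"
            )
        sid = row[0].strip()
        if not sid:
            raise ParseError(f"row {rownum}: empty sample ID")
        if sid in seen:
            raise ValidationError(f"duplicate sample ID {sid!r} (row {rownum})")
        seen.add(sid)
        calls: list[tuple[str, str] | None] = []
        for i, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell in missing_tokens:
                calls.append(MISSING)
                continue
            parts = cell.split(pair_sep)
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(
                    f"row {rownum}: cell {cell!r} for variant "
                    f"{variant_ids[i]!r} is not a two-allele pair"
                )
            a, b = sorted(p.strip() for p in parts)
            observed[i].update((a, b))
            calls.append((a, b))
        records.append(GenotypeRecord(sample_id=sid, calls=tuple(calls)))

    panel = VariantPanel(
        variant_ids=variant_ids,
        alleles_observed=tuple(frozenset(s) for s in observed),
    )
    return panel, records


def write_genotype_table(
    panel: VariantPanel,
    records: Sequence[GenotypeRecord],
    stream: IO[str],
    delimiter: str = ",",
    pair_sep: str = "/",
    missing_token: str = "./.",
) -> None:
    w = csv.writer(stream, delimiter=delimiter, lineterminator="\n")
    w.writerow(["ID", *panel.variant_ids])
    for rec in records:
        cells = [
            missing_token if c is None else f"{c[0]}{pair_sep}{c[1]}"
            for c in rec.calls
        ]
        w.writerow([rec.sample_id, *cells])


# ---------------------------------------------------------------------------
# Allele reference file
# ---------------------------------------------------------------------------

def _normalise_function(label: str) -> str:
    key = label.strip().lower()
    for valid in VALID_FUNCTIONS:
        if key == valid.lower():
            return valid
    raise ValidationError(
        f"unknown function label {label!r}; expected one of {VALID_FUNCTIONS}"
    )


def read_allele_definitions(
    stream: IO[str] | Iterable[str],
    panel: VariantPanel,
    delimiter: str | None = None,
) -> AlleleDefinitionTable:
    """Parse the star-allele reference file against an already-loaded panel.

    Column contract: star name, function, activity, then one allele column
    per panel variant in panel order.  A header row is tolerated (detected by
    a non-numeric activity column).  Duplicate haplotype vectors load but
    raise an :class:`AmbiguityWarning` naming the group.
    """
    lines = _as_lines(stream)
    if not lines:
        raise ParseError("empty allele reference file")
    rows, _ = _rows(lines, delimiter)

    # header row: non-numeric activity column and a first cell that does not
    # look like a star-allele name
    start = 0
    first = rows[0]
    if len(first) > 2 and not _is_float(first[2]) and not first[0].strip().startswith("*"):
        start = 1

    n_expected = 3 + len(panel)
    defs: list[AlleleDefinition] = []
    for rownum, row in enumerate(rows[start:], start=start + 1):
        if len(row) != n_expected:
            raise ValidationError(
                f"row {rownum}: expected {n_expected} columns (star, function, "
                f"activity, then one allele per panel variant in the same order "
                f"as the genotype file), found {len(row)}"
            )
        star = row[0].strip()
        if not star:
            raise ValidationError(f"row {rownum}: empty star allele name")
        function = _normalise_function(row[1])
        try:
            activity = float(row[2])
        except ValueError:
            raise ValidationError(
                f"row {rownum}: activity {row[2]!r} is not a number"
            ) from None
        if activity < 0:
            raise ValidationError(f"row {rownum}: negative activity value")
        hap = tuple(c.strip() for c in row[3:])
        if any(not a for a in hap):
            raise ValidationError(f"row {rownum}: empty allele string")
        defs.append(
            AlleleDefinition(star=star, function=function, activity=activity, haplotype=hap)
        )
    return AlleleDefinitionTable.build(panel, defs)


def write_allele_definitions(
    table: AlleleDefinitionTable, stream: IO[str], delimiter: str = ","
) -> None:
    w = csv.writer(stream, delimiter=delimiter, lineterminator="\n")
    w.writerow(["star", "function", "activity", *table.panel.variant_ids])
    for d in table.definitions:
        w.writerow([d.star, d.function, _fmt_activity(d.activity), *d.haplotype])


# ---------------------------------------------------------------------------
# CNV table
# ---------------------------------------------------------------------------

def read_cnv_table(
    stream: IO[str] | Iterable[str], delimiter: str | None = None
) -> list[CnvRecord]:
    """Parse a two-column (sample ID, integer copy number) table.

    Comma or tab delimiter is auto-detected; an optional header row is
    skipped.  Non-integer or negative copy numbers and duplicate sample IDs
    are validation errors.
    """
    lines = _as_lines(stream)
    rows, _ = _rows(lines, delimiter)
    records: list[CnvRecord] = []
    seen: set[str] = set()
    for rownum, row in enumerate(rows, start=1):
        if len(row) != 2:
            raise ParseError(f"row {rownum}: expected 2 fields, found {len(row)}")
        sid, raw = row[0].strip(), row[1].strip()
        if rownum == 1 and not _is_float(raw):
            continue  # header
        if not _is_int(raw):
            raise ValidationError(
                f"row {rownum}: copy number {raw!r} is not an integer"
            )
        copies = int(raw)
        if copies < 0:
            raise ValidationError(f"row {rownum}: negative copy number {copies}")
        if sid in seen:
            raise ValidationError(f"duplicate sample ID {sid!r} in CNV table")
        seen.add(sid)
        records.append(CnvRecord(sample_id=sid, copies=copies))
    return records


def _is_int(s: str) -> bool:
    try:
        int(s)
    except ValueError:
        return False
    return True


def _is_float(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def write_cnv_table(
    records: Sequence[CnvRecord], stream: IO[str], delimiter: str = ","
) -> None:
    w = csv.writer(stream, delimiter=delimiter, lineterminator="\n")
    w.writerow(["ID", "CNV"])
    for rec in records:
        w.writerow([rec.sample_id, rec.copies])


def cnv_lookup(records: Sequence[CnvRecord]) -> dict[str, int]:
    """Sample-ID → copies map; callers treat absent samples as 2 copies."""
    return {r.sample_id: r.copies for r in records}


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "sample_id",
    "haplotype_1",
    "haplotype_2",
    "cnv",
    "diplotype",
    "activity_score",
    "phenotype",
    "phase_posterior",
    "flags",
)


def _fmt_activity(v: float) -> str:
    # "1.0" rather than "1" or "1.00"; quarter-unit values print exactly.
    if v == int(v):
        return f"{v:.1f}"
    return f"{v:g}"


def write_report(calls: Sequence, stream: IO[str]) -> None:
    """Write the per-sample report CSV (header always present).

    ``calls`` are :class:`haplostar.phenotype.DiplotypeCall` objects; only
    their public attributes are used, so any structurally compatible object
    works.
    """
    w = csv.writer(stream, lineterminator="\n")
    w.writerow(REPORT_COLUMNS)
    for c in calls:
        activity = c.activity
        as_text = (
            "indeterminate" if activity.value is None else _fmt_activity(activity.value)
        )
        w.writerow(
            [
                c.sample_id,
                c.star1_label,
                c.star2_label,
                c.cnv,
                c.diplotype,
                as_text,
                c.phenotype,
                f"{c.posterior:.6f}",
                ";".join(c.flags),
            ]
        )


def read_report(stream: IO[str] | Iterable[str]) -> list[dict[str, str]]:
    """Parse a report CSV back into row dictionaries (all values strings)."""
    lines = _as_lines(stream)
    rows = list(csv.reader(lines))
    if not rows:
        raise ParseError("empty report file")
    header = tuple(rows[0])
    if header != REPORT_COLUMNS:
        raise FormatError(f"unexpected report header {header!r}")
    out = []
    for row in rows[1:]:
        if len(row) != len(header):
            raise ParseError("ragged report row")
        out.append(dict(zip(header, row)))
    return out


# ---------------------------------------------------------------------------
# PHASE dialect
# ---------------------------------------------------------------------------

def write_phase_input(
    panel: VariantPanel, records: Sequence[GenotypeRecord], stream: IO[str]
) -> None:
    """Emit the classic PHASE 2.1.1 input dialect.

    Line 1: individual count; line 2: locus count; line 3: ``P`` followed by
    space-separated positions (ordinal 1..L — variant IDs are opaque labels);
    line 4: one locus-type character per locus (``S``); then per individual an
    ID line and two space-separated allele lines, ``?`` at missing sites.
    """
    stream.write(f"{len(records)}\n")
    stream.write(f"{len(panel)}\n")
    stream.write("P " + " ".join(str(i + 1) for i in range(len(panel))) + "\n")
    stream.write("S" * len(panel) + "\n")
    for rec in records:
        stream.write(rec.sample_id + "\n")
        top = [("?" if c is None else c[0]) for c in rec.calls]
        bot = [("?" if c is None else c[1]) for c in rec.calls]
        stream.write(" ".join(top) + "\n")
        stream.write(" ".join(bot) + "\n")


def read_phase_output(
    stream: IO[str] | Iterable[str],
    panel: VariantPanel,
    expected_n: int | None = None,
) -> list[tuple[str, tuple[tuple[str, ...], tuple[str, ...]]]]:
    """Parse the best-pairs section of a PHASE output file.

    Accepts either a bare sequence of (ID line, haplotype line, haplotype
    line) triples or the same wrapped in ``BEGIN BESTPAIRS`` / ``END
    BESTPAIRS`` markers as the PHASE binary writes them.  ID lines of the
    form ``0 #S1`` or ``#S1`` yield sample ID ``S1``.

    Returns ordered ``(sample_id, (hap1, hap2))`` tuples.
    """
    lines = _as_lines(stream)
    body: list[str] = []
    in_section = False
    has_markers = any(ln.strip().upper().startswith("BEGIN BESTPAIRS") for ln in lines)
    for ln in lines:
        s = ln.strip()
        if s.upper().startswith("BEGIN BESTPAIRS"):
            in_section = True
            continue
        if s.upper().startswith("END BESTPAIRS"):
            in_section = False
            continue
        if has_markers and not in_section:
            continue
        body.append(s)
    if len(body) % 3 != 0:
        raise FormatError(
            f"best-pairs section has {len(body)} lines; expected a multiple of 3"
        )
    out: list[tuple[str, tuple[tuple[str, ...], tuple[str, ...]]]] = []
    for i in range(0, len(body), 3):
        id_line, h1_line, h2_line = body[i], body[i + 1], body[i + 2]
        sid = id_line.split("#", 1)[1].strip() if "#" in id_line else id_line.strip()
        h1 = tuple(h1_line.split())
        h2 = tuple(h2_line.split())
        if len(h1) != len(panel) or len(h2) != len(panel):
            raise FormatError(
                f"haplotype row for {sid!r} has wrong locus count "
                f"(expected {len(panel)})"
            )
        out.append((sid, (h1, h2)))
    if expected_n is not None and len(out) != expected_n:
        raise FormatError(
            f"best-pairs section lists {len(out)} individuals, expected {expected_n}"
        )
    return out
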