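"""Copy-number adjustment, activity score, and metabolizer phenotype.

The activity score (AS) of a diplotype is the sum of the activity values of
the gene copies an individual carries.  With the default two copies this is
``act(allele1) + act(allele2)``.  Copy-number variation changes the sum:

* deletion to one copy replaces one star allele with *5 (absent gene,
  activity 0) — a true one-copy gene yields apparently homozygous genotype
  calls, so a heterozygous call under cnv=1 is flagged as a conflict, not
  silently resolved;
* zero copies is treated as homozygous deletion *5/*5 (flagged, since a
  whole-cohort assay reporting cnv=0 usually deserves scrutiny);
* duplication (cnv = n >= 3) with two identical star alleles A multiplies:
  AS = n * act(A), rendered ``Ax(n-1)/A``;
* duplication with two *different* alleles cannot identify which allele is
  duplicated, so the AS is indeterminate; we additionally report the bounds
  the unknown assignment implies.

The AS maps to a metabolizer phenotype — poor (PM), intermediate (IM),
normal (NM), ultrarapid (UM) — by interval lookup against a validated
partition of [0, inf).  The default breakpoints are the CPIC activity-score
consensus (PM: AS = 0; IM: 0 < AS < 1.25; NM: 1.25 <= AS <= 2.25;
UM: AS > 2.25); they are configuration values and can be overridden from a
threshold file.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from .errors import ConfigError
from .io import DELETION_STAR, AlleleDefinitionTable, _as_lines, _fmt_activity
from .phasing import PhasedPair
from .stars import FLAG_AMBIGUOUS, FLAG_NO_CALL, StarMatch, render_diplotype

PHENOTYPE_INDETERMINATE = "Indeterminate"

FLAG_HEMIZYGOSITY_CONFLICT = "hemizygosity_conflict"
FLAG_CNV_ZERO = "cnv_zero_deletion"
FLAG_INDETERMINATE_DUP = "indeterminate_duplication"
FLAG_BOUNDS_CLASSIFIED = "bounds_classified"

_FLAG_ORDER = (
    "phase_tie",
    "uninformative_phase",
    FLAG_NO_CALL,
    FLAG_AMBIGUOUS,
    FLAG_HEMIZYGOSITY_CONFLICT,
    FLAG_CNV_ZERO,
    FLAG_INDETERMINATE_DUP,
    FLAG_BOUNDS_CLASSIFIED,
)


# ---------------------------------------------------------------------------
# Activity score value
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityScore:
    """A numeric AS, or an indeterminate one with optional [lo, hi] bounds."""

    value: float | None
    bounds: tuple[float, float] | None = None

    @classmethod
    def of(cls, value: float) -> "ActivityScore":
        return cls(value=float(value))

    @classmethod
    def indeterminate(
        cls, bounds: tuple[float, float] | None = None
    ) -> "ActivityScore":
        return cls(value=None, bounds=bounds)

    @property
    def is_indeterminate(self) -> bool:
        return self.value is None

    def __str__(self) -> str:
        if self.value is None:
            return "indeterminate"
        return _fmt_activity(self.value)


# ---------------------------------------------------------------------------
# Phenotype thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """One phenotype interval; ``lo``/``hi`` with per-end openness."""

    category: str
    lo: float
    hi: float
    lo_open: bool
    hi_open: bool

    def contains(self, x: float) -> bool:
        above = x > self.lo if self.lo_open else x >= self.lo
        below = x < self.hi if self.hi_open else x <= self.hi
        return above and below


@dataclass(frozen=True)
class PhenotypeThresholds:
    """A validated partition of AS in [0, inf) into phenotype categories.

    Bands must be contiguous, non-overlapping, ordered slow-to-fast
    metabolism, start at 0 (closed, so AS = 0 always classifies) and end at
    infinity.  Malformed partitions fail here, at load time — never during
    classification.
    """

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigError("no phenotype bands")
        first, last = self.bands[0], self.bands[-1]
        if first.lo != 0.0 or first.lo_open:
            raise ConfigError("first band must start at 0 (closed)")
        if not math.isinf(last.hi):
            raise ConfigError("last band must extend to infinity")
        for b in self.bands:
            if b.lo > b.hi or (b.lo == b.hi and (b.lo_open or b.hi_open)):
                raise ConfigError(f"band {b.category}: empty interval")
        for a, b in zip(self.bands, self.bands[1:]):
            if a.hi != b.lo:
                raise ConfigError(
                    f"gap or overlap between {a.category} and {b.category}"
                )
            if a.hi_open == b.lo_open:
                raise ConfigError(
                    f"boundary {a.hi} must belong to exactly one of "
                    f"{a.category}/{b.category}"
                )

    @classmethod
    def default(cls) -> "PhenotypeThresholds":
        inf = math.inf
        return cls(
            bands=(
                Band("PM", 0.0, 0.0, False, False),
                Band("IM", 0.0, 1.25, True, True),
                Band("NM", 1.25, 2.25, False, False),
                Band("UM", 2.25, inf, True, True),
            )
        )

    @classmethod
    def from_file(cls, stream: IO[str] | Iterable[str]) -> "PhenotypeThresholds":
        """Load bands from CSV rows ``category,lower,upper,lower_end,upper_end``
        with each end marked ``open`` or ``closed``; ``inf`` is a legal upper
        bound.  A header row is tolerated."""
        lines = _as_lines(stream)
        rows = list(csv.reader(lines))
        bands: list[Band] = []
        for i, row in enumerate(rows, start=1):
            if len(row) != 5:
                raise ConfigError(f"threshold row {i}: expected 5 fields")
            cat, lo_s, hi_s, lo_end, hi_end = (c.strip() for c in row)
            if i == 1 and not _is_float(lo_s):
                continue  # header
            if lo_end.lower() not in ("open", "closed") or hi_end.lower() not in (
                "open",
                "closed",
            ):
                raise ConfigError(
                    f"threshold row {i}: bound openness must be open/closed"
                )
            bands.append(
                Band(
                    category=cat,
                    lo=float(lo_s),
                    hi=float(hi_s),
                    lo_open=lo_end.lower() == "open",
                    hi_open=hi_end.lower() == "open",
                )
            )
        return cls(bands=tuple(bands))

    def classify_value(self, x: float) -> str:
        for b in self.bands:
            if b.contains(x):
                return b.category
        raise ConfigError(f"activity score {x} outside configured bands")


def _is_float(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def classify_phenotype(score: ActivityScore, thresholds: PhenotypeThresholds) -> str:
    """Map an AS (possibly indeterminate-with-bounds) to a phenotype category.

    Indeterminate scores yield ``Indeterminate`` unless both bounds fall in
    one category, in which case that category is returned (callers add a
    bounds-derived note flag).
    """
    if score.value is not None:
        if score.value < 0:
            raise ConfigError("activity score must be non-negative")
        return thresholds.classify_value(score.value)
    if score.bounds is not None:
        lo_cat = thresholds.classify_value(score.bounds[0])
        hi_cat = thresholds.classify_value(score.bounds[1]) if not math.isinf(
            score.bounds[1]
        ) else thresholds.bands[-1].category
        if lo_cat == hi_cat:
            return lo_cat
    return PHENOTYPE_INDETERMINATE


# ---------------------------------------------------------------------------
# CNV adjustment
# ---------------------------------------------------------------------------

KIND_NORMAL = "normal"
KIND_DELETION = "deletion"
KIND_NULL = "null"
KIND_DUPLICATION = "duplication"
KIND_INDETERMINATE_DUP = "indeterminate_duplication"


@dataclass(frozen=True)
class AdjustedDiplotype:
    """A diplotype after applying the copy-number rules.

    ``match1``/``match2`` are the star matches of the two gene copies, with
    ``None`` standing for a deleted copy (*5).  ``labels`` carry the
    rendered names including any ``xN`` duplication suffix.
    """

    kind: str
    cnv: int
    match1: StarMatch | None
    match2: StarMatch | None
    labels: tuple[str, str]
    flags: tuple[str, ...] = ()

    @property
    def diplotype(self) -> str:
        if self.kind == KIND_DUPLICATION:
            # keep the duplicated copy first: "*1x2/*1"
            return f"{self.labels[0]}/{self.labels[1]}"
        return render_diplotype(*self.labels)


def apply_cnv(
    matches: tuple[StarMatch, StarMatch], pair: PhasedPair, cnv: int
) -> AdjustedDiplotype:
    """Apply the copy-number rules to a called diplotype.

    cnv=2 (the default) leaves the calls unchanged.  cnv=1 requires an
    apparently homozygous genotype and replaces one allele with *5; a
    heterozygous genotype under cnv=1 keeps both calls and raises a
    hemizygosity-conflict flag.  cnv=0 becomes *5/*5.  cnv>=3 with two
    identical calls assigns the duplication to that allele; with different
    calls the duplicated allele cannot be identified and the result is
    indeterminate.  Conflicts are flags, never exceptions.
    """
    if cnv < 0:
        raise ConfigError("copy number must be non-negative")
    m1, m2 = matches
    if cnv == 0:
        return AdjustedDiplotype(
            kind=KIND_NULL,
            cnv=cnv,
            match1=None,
            match2=None,
            labels=(DELETION_STAR, DELETION_STAR),
            flags=(FLAG_CNV_ZERO,),
        )
    if cnv == 1:
        if pair.h1 == pair.h2:
            return AdjustedDiplotype(
                kind=KIND_DELETION,
                cnv=cnv,
                match1=m1,
                match2=None,
                labels=(m1.label, DELETION_STAR),
            )
        return AdjustedDiplotype(
            kind=KIND_NORMAL,
            cnv=cnv,
            match1=m1,
            match2=m2,
            labels=(m1.label, m2.label),
            flags=(FLAG_HEMIZYGOSITY_CONFLICT,),
        )
    if cnv == 2:
        return AdjustedDiplotype(
            kind=KIND_NORMAL,
            cnv=cnv,
            match1=m1,
            match2=m2,
            labels=(m1.label, m2.label),
        )
    # cnv >= 3: duplication / multiplication
    if not m1.is_nocall and not m2.is_nocall and set(m1.names) == set(m2.names):
        label = m1.label
        return AdjustedDiplotype(
            kind=KIND_DUPLICATION,
            cnv=cnv,
            match1=m1,
            match2=m2,
            labels=(f"{label}x{cnv - 1}", label),
        )
    return AdjustedDiplotype(
        kind=KIND_INDETERMINATE_DUP,
        cnv=cnv,
        match1=m1,
        match2=m2,
        labels=(m1.label, m2.label),
        flags=(FLAG_INDETERMINATE_DUP,),
    )


def _match_activity_range(
    match: StarMatch | None, table: AlleleDefinitionTable
) -> tuple[float, float] | None:
    """[min, max] activity of a gene copy; None for a no-call copy."""
    if match is None:
        return (0.0, 0.0)  # deleted copy contributes nothing
    if match.is_nocall:
        return None
    acts = [table.activity_of(n) for n in match.names]
    return (min(acts), max(acts))


def activity_score(
    adjusted: AdjustedDiplotype, table: AlleleDefinitionTable
) -> ActivityScore:
    """Compute the AS of a CNV-adjusted diplotype.

    Up to two copies: the sum of the copies' activities (*5 contributes 0).
    Homozygous duplication with n copies of allele A: ``n * act(A)``.
    Heterozygous duplication: indeterminate, with bounds
    ``[act(A)+act(B)+(n-2)*min, act(A)+act(B)+(n-2)*max]``.  Any no-call
    copy makes the AS indeterminate.  Ambiguity groups whose members share
    one activity value score normally; otherwise the group's [min, max]
    spread propagates into bounds.
    """
    r1 = _match_activity_range(adjusted.match1, table)
    r2 = _match_activity_range(adjusted.match2, table)
    if r1 is None or r2 is None:
        return ActivityScore.indeterminate()
    n = adjusted.cnv
    if adjusted.kind == KIND_DUPLICATION:
        lo, hi = n * r1[0], n * r1[1]
    elif adjusted.kind == KIND_INDETERMINATE_DUP:
        lo = r1[0] + r2[0] + (n - 2) * min(r1[0], r2[0])
        hi = r1[1] + r2[1] + (n - 2) * max(r1[1], r2[1])
    else:
        lo, hi = r1[0] + r2[0], r1[1] + r2[1]
    if lo == hi and adjusted.kind != KIND_INDETERMINATE_DUP:
        return ActivityScore.of(lo)
    return ActivityScore.indeterminate(bounds=(lo, hi))


# ---------------------------------------------------------------------------
# Per-sample assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiplotypeCall:
    """Everything the report prints for one sample."""

    sample_id: str
    diplotype: str
    star1_label: str
    star2_label: str
    cnv: int
    activity: ActivityScore
    phenotype: str
    posterior: float
    flags: tuple[str, ...]


def assemble_call(
    pair: PhasedPair,
    matches: tuple[StarMatch, StarMatch],
    cnv: int,
    table: AlleleDefinitionTable,
    thresholds: PhenotypeThresholds,
) -> DiplotypeCall:
    """Run CNV adjustment, AS and phenotype for one phased, matched sample."""
    adjusted = apply_cnv(matches, pair, cnv)
    score = activity_score(adjusted, table)
    phenotype = classify_phenotype(score, thresholds)

    flags: set[str] = set(pair.flags) | set(adjusted.flags)
    for m in (adjusted.match1, adjusted.match2):
        if m is None:
            continue
        if m.is_nocall:
            flags.add(FLAG_NO_CALL)
        if m.ambiguous:
            flags.add(FLAG_AMBIGUOUS)
    if score.is_indeterminate and phenotype != PHENOTYPE_INDETERMINATE:
        flags.add(FLAG_BOUNDS_CLASSIFIED)

    ordered = tuple(f for f in _FLAG_ORDER if f in flags) + tuple(
        sorted(flags - set(_FLAG_ORDER))
    )
    return DiplotypeCall(
        sample_id=pair.sample_id,
        diplotype=adjusted.diplotype,
        star1_label=adjusted.labels[0],
        star2_label=adjusted.labels[1],
        cnv=cnv,
        activity=score,
        phenotype=phenotype,
        posterior=pair.posterior,
        flags=ordered,
    )
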