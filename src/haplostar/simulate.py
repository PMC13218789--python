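"""Synthetic cohorts with known truth for benchmarking the pipeline.

The generator draws each sample's two star alleles independently from a
star-allele frequency vector (Hardy–Weinberg pairing — the same random-
mating model the phaser assumes, so parameter-recovery experiments are
well-posed), materializes the defining haplotype vectors from an allele
reference table, collapses them to unordered genotype calls, optionally
masks sites at a missing rate, and draws a gene copy number.  Truth
diplotypes, activity scores and phenotypes are computed through the same
copy-number/scoring rules the caller applies, so truth is exactly
reproducible from the truth star pair.

Haplotypes are drawn only from table rows: star-allele calling is closed
over the reference file, so the simulation matches its universe.  An
optional ``novel_rate`` injects off-table vectors (one random site
mutated to a private allele) to exercise the NO_CALL path.

Two reference fixtures ship with the package:

* :func:`toy_reference` — a 3-variant, 4-star table for worked examples;
* :func:`cyp2d6_demo_reference` — a 12-variant panel with 13
  vector-defined star alleles mirroring a targeted CYP2D6 assay (plus *5,
  which as a whole-gene deletion has no vector and enters only through the
  CNV channel), with CPIC-style activity values and a realistic allele
  frequency vector for an admixed population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np

from .errors import ValidationError
from .io import (
    MISSING,
    AlleleDefinitionTable,
    CnvRecord,
    GenotypeRecord,
    VariantPanel,
    read_allele_definitions,
    read_genotype_table,
)
from .phasing import PhasedPair
from .phenotype import (
    ActivityScore,
    DiplotypeCall,
    PhenotypeThresholds,
    assemble_call,
)
from .stars import StarMatch


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``star_freqs`` must sum to 1 and reference only table stars;
    ``cnv_spec`` maps copy number to probability (default: everyone carries
    two copies).  Everything is reproducible from ``seed``.
    """

    star_freqs: dict[str, float]
    n_samples: int
    missing_rate: float = 0.0
    cnv_spec: dict[int, float] = field(default_factory=lambda: {2: 1.0})
    seed: int = 0
    novel_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")
        if abs(sum(self.star_freqs.values()) - 1.0) > 1e-9:
            raise ValidationError("star frequencies must sum to 1")
        if abs(sum(self.cnv_spec.values()) - 1.0) > 1e-9:
            raise ValidationError("cnv probabilities must sum to 1")
        if any(c < 0 for c in self.cnv_spec):
            raise ValidationError("negative copy number in cnv_spec")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated sample."""

    sample_id: str
    star1: str
    star2: str
    cnv: int
    diplotype: str
    activity: ActivityScore
    phenotype: str


def _truth_call(
    sid: str,
    haps: tuple[tuple[str, ...], tuple[str, ...]],
    cnv: int,
    table: AlleleDefinitionTable,
    thresholds: PhenotypeThresholds,
) -> DiplotypeCall:
    h1, h2 = sorted(haps)
    pair = PhasedPair(sample_id=sid, h1=h1, h2=h2, posterior=1.0, n_resolutions=1)
    matches = (
        StarMatch(names=table.by_haplotype.get(h1, ())),
        StarMatch(names=table.by_haplotype.get(h2, ())),
    )
    return assemble_call(pair, matches, cnv, table, thresholds)


def generate_cohort(
    config: SimulationConfig,
    table: AlleleDefinitionTable,
    thresholds: PhenotypeThresholds | None = None,
) -> tuple[list[GenotypeRecord], list[CnvRecord], list[TruthRecord]]:
    """Draw a cohort and its ground truth.

    Copy-number handling mirrors what a real assay would see: a one-copy
    sample genotypes as homozygous for its single haplotype (truth pairs it
    with *5); a zero-copy sample yields no genotype calls at all (all
    sites missing) and truth *5/*5; duplications leave the genotype
    unchanged (an unordered allele-pair assay cannot count copies) and
    enter truth through the copy-number rules.
    """
    thresholds = thresholds or PhenotypeThresholds.default()
    for star in config.star_freqs:
        if star not in table.by_star:
            raise ValidationError(f"star {star!r} not in allele definition table")

    rng = np.random.default_rng(config.seed)
    star_names = sorted(config.star_freqs, key=lambda s: table.by_star[s].star)
    probs = np.array([config.star_freqs[s] for s in star_names])
    probs = probs / probs.sum()
    cnv_values = sorted(config.cnv_spec)
    cnv_probs = np.array([config.cnv_spec[c] for c in cnv_values], dtype=float)
    cnv_probs = cnv_probs / cnv_probs.sum()
    n_var = len(table.panel)
    width = len(str(config.n_samples))

    genotypes: list[GenotypeRecord] = []
    cnvs: list[CnvRecord] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_samples):
        sid = f"S{i + 1:0{width}d}"
        cnv = int(cnv_values[rng.choice(len(cnv_values), p=cnv_probs)])

        if cnv == 0:
            calls: list[tuple[str, str] | None] = [MISSING] * n_var
            truth_haps = None
        else:
            if cnv == 1:
                s1 = s2 = star_names[rng.choice(len(star_names), p=probs)]
            else:
                s1 = star_names[rng.choice(len(star_names), p=probs)]
                s2 = star_names[rng.choice(len(star_names), p=probs)]
            h1 = list(table.by_star[s1].haplotype)
            h2 = list(table.by_star[s2].haplotype)
            if config.novel_rate > 0.0 and rng.random() < config.novel_rate:
                site = int(rng.integers(n_var))
                h1[site] = h1[site] + "_novel"
            calls = [tuple(sorted((a, b))) for a, b in zip(h1, h2)]
            if config.missing_rate > 0.0:
                mask = rng.random(n_var) < config.missing_rate
                calls = [MISSING if m else c for c, m in zip(calls, mask)]
            truth_haps = (tuple(h1), tuple(h2))

        genotypes.append(GenotypeRecord(sample_id=sid, calls=tuple(calls)))
        cnvs.append(CnvRecord(sample_id=sid, copies=cnv))

        if truth_haps is None:
            ref = table.definitions[0].haplotype  # placeholder pair, unused by cnv=0 rule
            truth_haps = (ref, ref)
        call = _truth_call(sid, truth_haps, cnv, table, thresholds)
        truths.append(
            TruthRecord(
                sample_id=sid,
                star1=call.star1_label,
                star2=call.star2_label,
                cnv=cnv,
                diplotype=call.diplotype,
                activity=call.activity,
                phenotype=call.phenotype,
            )
        )
    return genotypes, cnvs, truths


def inject_missing(
    records: list[GenotypeRecord], rate: float, seed: int
) -> list[GenotypeRecord]:
    """Independently mask each site as missing with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValidationError("rate must be in [0, 1)")
    if rate == 0.0:
        return list(records)
    rng = np.random.default_rng(seed)
    out: list[GenotypeRecord] = []
    for rec in records:
        mask = rng.random(len(rec.calls)) < rate
        calls = tuple(
            MISSING if m else c for c, m in zip(rec.calls, mask)
        )
        out.append(GenotypeRecord(sample_id=rec.sample_id, calls=calls))
    return out


def true_haplotype_frequencies(
    config: SimulationConfig, table: AlleleDefinitionTable
) -> dict[tuple[str, ...], float]:
    """The haplotype frequency vector implied by ``star_freqs``."""
    out: dict[tuple[str, ...], float] = {}
    for star, f in config.star_freqs.items():
        out[table.by_star[star].haplotype] = out.get(table.by_star[star].haplotype, 0.0) + f
    return out


# ---------------------------------------------------------------------------
# Shipped reference fixtures
# ---------------------------------------------------------------------------

_TOY_REFERENCE_CSV = """\
star,function,activity,v1,v2,v3
*1,Normal,1.0,C,G,G
*4,No function,0.0,C,A,G
*10,Decreased,0.25,T,G,G
*41,Decreased,0.5,C,G,A
"""

_TOY_GENOTYPE_HEADER = "ID,v1,v2,v3"


def toy_reference() -> AlleleDefinitionTable:
    """A 3-variant, 4-star reference table for worked examples and tests."""
    panel = VariantPanel(
        variant_ids=("v1", "v2", "v3"),
        alleles_observed=(
            frozenset({"C", "T"}),
            frozenset({"G", "A"}),
            frozenset({"G", "A"}),
        ),
    )
    return read_allele_definitions(StringIO(_TOY_REFERENCE_CSV), panel)


# A 12-variant panel in the style of a targeted CYP2D6 assay.  Variant IDs
# follow the usual M33388 cDNA-relative naming; the defining combinations
# are synthetic stand-ins with the familiar structure (e.g. *4 carries
# 1846G>A on a *10-like background, *41 is 2988G>A on a *2 backbone).
_DEMO_PANEL_IDS = (
    "31G>A",
    "100C>T",
    "1023C>T",
    "1659G>A",
    "1707delT",
    "1846G>A",
    "2549delA",
    "2615delAAG",
    "2850C>T",
    "2988G>A",
    "3183G>A",
    "4180G>C",
)

_DEMO_REFERENCE_CSV = """\
star,function,activity,31G>A,100C>T,1023C>T,1659G>A,1707delT,1846G>A,2549delA,2615delAAG,2850C>T,2988G>A,3183G>A,4180G>C
*1,Normal,1.0,G,C,C,G,T,G,A,AAG,C,G,G,G
*2,Normal,1.0,G,C,C,G,T,G,A,AAG,T,G,G,C
*3,No function,0.0,G,C,C,G,T,G,del,AAG,C,G,G,G
*4,No function,0.0,G,T,C,G,T,A,A,AAG,C,G,G,C
*6,No function,0.0,G,C,C,G,del,G,A,AAG,C,G,G,G
*9,Decreased,0.5,G,C,C,G,T,G,A,del,C,G,G,G
*10,Decreased,0.25,G,T,C,G,T,G,A,AAG,C,G,G,C
*17,Decreased,0.5,G,C,T,G,T,G,A,AAG,T,G,G,C
*29,Decreased,0.5,G,C,C,A,T,G,A,AAG,T,G,A,C
*34,Normal,1.0,G,C,C,G,T,G,A,AAG,T,G,G,G
*35,Normal,1.0,A,C,C,G,T,G,A,AAG,T,G,G,C
*39,Normal,1.0,G,C,C,G,T,G,A,AAG,C,G,G,C
*41,Decreased,0.5,G,C,C,G,T,G,A,AAG,T,A,G,C
"""

#: Star-allele frequencies typical of an admixed, partly African-ancestry
#: population, normalized to the 13 vector-defined stars of the demo table.
DEMO_STAR_FREQUENCIES: dict[str, float] = {
    "*1": 0.31,
    "*2": 0.20,
    "*4": 0.12,
    "*17": 0.10,
    "*29": 0.06,
    "*41": 0.06,
    "*10": 0.05,
    "*35": 0.03,
    "*39": 0.02,
    "*9": 0.02,
    "*3": 0.01,
    "*6": 0.01,
    "*34": 0.01,
}


def cyp2d6_demo_reference() -> AlleleDefinitionTable:
    """The shipped 12-variant CYP2D6-style demo reference table."""
    panel, _ = read_genotype_table([ "ID," + ",".join(_DEMO_PANEL_IDS) ])
    return read_allele_definitions(StringIO(_DEMO_REFERENCE_CSV), panel)
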