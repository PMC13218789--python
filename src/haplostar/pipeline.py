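"""End-to-end orchestration: files in, report + summary out.

The full workflow is read → joint EM phasing → per-sample phase → star
matching → copy-number rules → activity score → phenotype → report.  The
pipeline is deterministic for a fixed seed: reports are byte-identical
across runs.  Output is composed in memory and written last, so a failing
stage never leaves a partial report behind.

Samples with a recorded copy number of 0 carry no gene to phase; they are
excluded from the EM cohort and reported directly as *5/*5.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Sequence

from .io import (
    AlleleDefinitionTable,
    CnvRecord,
    GenotypeRecord,
    VariantPanel,
    cnv_lookup,
    read_allele_definitions,
    read_cnv_table,
    read_genotype_table,
    write_report,
)
from .phasing import EMOptions, HaplotypeFrequencySet, PhasedPair, em_estimate, phase_cohort
from .phenotype import DiplotypeCall, PhenotypeThresholds, assemble_call
from .stars import StarMatch, call_diplotype

logger = logging.getLogger("haplostar")


@dataclass
class RunConfig:
    """Paths and options for one pipeline run."""

    genotypes: str | Path
    alleles: str | Path
    cnv: str | Path | None = None
    thresholds: str | Path | None = None
    out: str | Path | None = None
    summary: str | Path | None = None
    delimiter: str | None = None
    pair_sep: str = "/"
    missing_token: str | None = None
    tol: float = 1e-8
    max_iter: int = 1000
    restarts: int = 3
    seed: int = 0
    het_cap: int = 15

    def em_options(self) -> EMOptions:
        return EMOptions(
            tol=self.tol,
            max_iter=self.max_iter,
            n_restarts=self.restarts,
            seed=self.seed,
            het_cap=self.het_cap,
        )


@dataclass
class PipelineResult:
    """In-memory result of a run: calls in input order plus diagnostics."""

    calls: list[DiplotypeCall]
    freqs: HaplotypeFrequencySet | None
    panel: VariantPanel
    table: AlleleDefinitionTable
    summary: dict = field(default_factory=dict)

    def report_text(self) -> str:
        buf = StringIO()
        write_report(self.calls, buf)
        return buf.getvalue()


def call_cohort(
    panel: VariantPanel,
    records: Sequence[GenotypeRecord],
    table: AlleleDefinitionTable,
    cnv_records: Sequence[CnvRecord] = (),
    thresholds: PhenotypeThresholds | None = None,
    opts: EMOptions | None = None,
) -> PipelineResult:
    """Run phasing → star calling → CNV/AS/phenotype on in-memory inputs."""
    thresholds = thresholds or PhenotypeThresholds.default()
    opts = opts or EMOptions()
    copies = cnv_lookup(cnv_records)

    if len(records) == 1:
        logger.warning(
            "cohort of size 1: joint phasing is uninformative; phase "
            "posteriors reflect only within-sample ambiguity"
        )

    wildcards = panel.union_alleles(table.alleles_by_site())
    phaseable = [r for r in records if copies.get(r.sample_id, 2) != 0]

    freqs: HaplotypeFrequencySet | None = None
    pairs_by_id: dict[str, PhasedPair] = {}
    if phaseable:
        freqs = em_estimate(phaseable, opts, wildcards=wildcards)
        for pair in phase_cohort(phaseable, freqs, het_cap=opts.het_cap):
            pairs_by_id[pair.sample_id] = pair
        logger.info(
            "phased %d samples over %d candidate haplotypes in %d EM "
            "iterations (loglik %.4f)",
            len(phaseable),
            len(freqs.freq),
            freqs.n_iterations,
            freqs.loglik,
        )

    placeholder = tuple("?" for _ in range(len(panel)))
    calls: list[DiplotypeCall] = []
    for rec in records:
        cnv = copies.get(rec.sample_id, 2)
        if cnv == 0:
            pair = PhasedPair(
                sample_id=rec.sample_id,
                h1=placeholder,
                h2=placeholder,
                posterior=1.0,
                n_resolutions=1,
            )
            matches: tuple[StarMatch, StarMatch] = (StarMatch(()), StarMatch(()))
        else:
            pair = pairs_by_id[rec.sample_id]
            matches = call_diplotype(pair, table)
        calls.append(assemble_call(pair, matches, cnv, table, thresholds))

    flag_counts: dict[str, int] = {}
    phenotype_counts: dict[str, int] = {}
    for c in calls:
        phenotype_counts[c.phenotype] = phenotype_counts.get(c.phenotype, 0) + 1
        for f in c.flags:
            flag_counts[f] = flag_counts.get(f, 0) + 1
    summary = {
        "n_samples": len(records),
        "n_variants": len(panel),
        "n_candidate_haplotypes": len(freqs.freq) if freqs else 0,
        "em_iterations": freqs.n_iterations if freqs else 0,
        "em_loglik": freqs.loglik if freqs else None,
        "phenotype_counts": dict(sorted(phenotype_counts.items())),
        "flag_counts": dict(sorted(flag_counts.items())),
    }
    return PipelineResult(
        calls=calls, freqs=freqs, panel=panel, table=table, summary=summary
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full file-to-file workflow described by ``config``.

    Reads the genotype table, allele reference (validated against the
    genotype column order), optional CNV table and optional threshold file;
    phases, calls, scores and classifies every sample; writes the report
    CSV and a machine-readable JSON summary if paths are configured.
    """
    read_kwargs: dict = {"delimiter": config.delimiter, "pair_sep": config.pair_sep}
    if config.missing_token is not None:
        read_kwargs["missing_tokens"] = frozenset(
            {config.missing_token, ""}
        )
    with open(config.genotypes, encoding="utf-8") as fh:
        panel, records = read_genotype_table(fh, **read_kwargs)
    with open(config.alleles, encoding="utf-8") as fh:
        table = read_allele_definitions(fh, panel, delimiter=config.delimiter)
    cnv_records: list[CnvRecord] = []
    if config.cnv is not None:
        with open(config.cnv, encoding="utf-8") as fh:
            cnv_records = read_cnv_table(fh)
    thresholds = PhenotypeThresholds.default()
    if config.thresholds is not None:
        with open(config.thresholds, encoding="utf-8") as fh:
            thresholds = PhenotypeThresholds.from_file(fh)

    result = call_cohort(
        panel,
        records,
        table,
        cnv_records=cnv_records,
        thresholds=thresholds,
        opts=config.em_options(),
    )

    report = result.report_text()  # composed before any file is touched
    if config.out is not None:
        Path(config.out).write_text(report, encoding="utf-8")
    if config.summary is not None:
        Path(config.summary).write_text(
            json.dumps(result.summary, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    return result
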