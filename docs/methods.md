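# Methods

## Scope and data model

haplostar converts unphased genotype tables from targeted CYP2D6 assays
into star-allele diplotypes, activity scores (AS) and metabolizer
phenotypes. The variant panel is defined by the genotype file's header;
variant IDs are opaque labels and are never parsed as genomic coordinates —
the only ordering contract is that the allele definition table lists its
allele columns in the same order. Genotype cells are unordered allele pairs
(`A/B`, separator configurable) or a missing token (`./.` by default, also
configurable); pairs are canonicalized lexicographically at load so that
file order cannot leak phase signal. Multiallelic variants are supported
because allele "strings" (e.g. `del`, `AAG`) are first-class: indels such
as 1707delT are CYP2D6-defining.

Sequencing-derived input (VCF) and CYP2D7 hybrid/gene-conversion events are
out of scope; the tool targets the unordered-pair output of qPCR-style
panels.

## Phasing model

Let `p = (p_1 … p_K)` be frequencies over the candidate haplotype support.
Under Hardy–Weinberg equilibrium (random mating, no inbreeding, one
population), an individual's genotype likelihood is the sum of
`c_kl p_k p_l` over compatible unordered pairs, `c_kl = 2` for
heterozygous pairs. The support is the union, over samples, of the pairs
compatible with each genotype; missing sites expand over the alleles
observed at that site in the cohort plus the allele reference — the same
semantics as `?` in PHASE input. A cap of `2^15` ordered phase
configurations per sample (≈15 heterozygous/missing-expanded sites) guards
against pathological inputs; 12-variant panels sit far below it.

`p` is estimated by EM:

* **E-step** — per sample, `P({k,l} | g_i, p) ∝ c_kl p_k p_l` over the
  sample's compatible pairs;
* **M-step** — `p_k = (1/2N) Σ_i Σ_{pairs ∋ k} mult_k(pair) · P(pair | g_i)`.

Iteration stops when the log-likelihood changes by less than `tol = 1e-8`
(default) or after 1000 iterations. The likelihood is multimodal in
principle; a perfectly symmetric cohort (e.g. a single doubly-heterozygous
sample) even makes the uniform initialization an exact saddle point of EM.
We therefore run 3 restarts by default — restart 0 from the uniform vector,
later restarts from seeded Dirichlet(1) draws — and keep the best final
log-likelihood. All randomness flows from one integer seed; the support is
sorted lexicographically, so results are invariant to sample order (and
byte-identical across runs and platforms for a fixed seed).

Each sample is then assigned the compatible pair maximizing
`P(pair | g_i, p̂)`; the reported posterior is that normalized probability.
Exact ties (relative tolerance 1e-9) resolve to the lexicographically
smallest pair and raise a `phase_tie` flag; a sample whose every compatible
pair has zero estimated mass gets a uniform posterior and an
`uninformative_phase` flag. Samples with at most one heterozygous site and
no missing data have a single resolution and always phase with posterior
exactly 1.

This replaces the external PHASE 2.1.1 binary with a native
maximum-likelihood phaser: the approximate-coalescent prior PHASE layers on
top of the HWE likelihood is deliberately not reproduced (it is a
population-genetic smoothing device, unmaintained as software and
unportable as a dependency). For users who want PHASE itself, the package
writes its classic input dialect and reads its best-pairs output, slotting
the binary's results into the rest of the pipeline unchanged. Phase
uncertainty is reported as the best pair plus its posterior; thresholding
is left to the user.

In floating-point arithmetic the EM ascent property holds to rounding; the
trace is recorded raw and tested non-decreasing with a 1e-9 slack.

## Star-allele matching

Matching is exact, site-wise equality against every definition-table row.
A haplotype absent from the table yields NO_CALL (rendered `*?`) and a
sample-level `no_call` flag — it is never defaulted to \*1, which would
fabricate a normal-function call from an absence of evidence. Tables may
contain rows with identical vectors (sub-alleles a panel cannot separate);
these load as an *ambiguity group*, are warned about at load time, and are
reported joined (`*2|*35`). A group whose members share one activity value
scores normally; otherwise the group's activity spread propagates into AS
bounds. Diplotype strings are rendered with the lower star number first
(`*1/*4`, never `*4/*1`).

## Copy-number rules and activity score

With `cnv` the user-supplied copy number (default 2 for absent samples):

| cnv | rule | AS |
|-----|------|----|
| 2 | unchanged | `act(a) + act(b)` |
| 1 | homozygous call required; one allele becomes \*5; heterozygous call keeps both and flags `hemizygosity_conflict` | `act(a)` |
| 0 | `*5/*5` (flagged `cnv_zero_deletion`; an extrapolation beyond single-copy deletion) | 0 |
| ≥3, identical alleles A | duplication assigned, rendered `Ax(n−1)/A` | `n · act(A)` |
| ≥3, different alleles | duplicated allele unidentifiable → indeterminate | bounds `[a+b+(n−2)·min, a+b+(n−2)·max]` |

Conflicts are flags, never exceptions: a cnv=1 record against a
heterozygous genotype most likely means a CNV-assay error, and the user —
not the pipeline — should adjudicate. Zero-copy samples carry no gene to
phase; they are excluded from the EM cohort and reported directly.

Indeterminate-duplication bounds are an optional extension beyond the bare
"indeterminate" verdict: when both bounds fall inside a single phenotype
category the category is reported with a `bounds_classified` note,
otherwise the phenotype stays `Indeterminate`.

## Phenotype thresholds

Thresholds are a validated partition of `[0, ∞)`: contiguous,
non-overlapping intervals with each boundary owned by exactly one side,
starting closed at 0 and reaching infinity. Defaults are the CPIC
activity-score consensus — PM `{0}`, IM `(0, 1.25)`, NM `[1.25, 2.25]`,
UM `(2.25, ∞)` — stored as configuration (overridable via
`category,lower,upper,lower_end,upper_end` CSV), never hard-coded in the
classification logic. Validation at load time guarantees classification is
total and monotone: a lower AS can never map to a faster category.

## Synthetic cohorts

The simulator draws each sample's two star alleles i.i.d. from a star
frequency vector (Hardy–Weinberg pairing — intentionally the same
random-mating model the phaser assumes, so parameter-recovery tests are
well-posed; model-mismatch robustness is a non-goal), materializes the
defining vectors, collapses them to unordered calls, masks sites at a
missing rate, and draws a copy number. One-copy samples genotype as
homozygous for their single haplotype; zero-copy samples yield all-missing
genotypes. Truth AS/phenotypes are computed through the same copy-number
and scoring rules as the caller, so truth is exactly reproducible from the
truth star pair. Haplotypes are drawn only from table rows — star-allele
calling is closed over the reference file — with an optional `novel_rate`
that mutates one site to a private allele to exercise the NO_CALL path.

The shipped demo reference mirrors a 12-variant targeted CYP2D6 panel with
13 vector-defined star alleles (\*1, \*2, \*3, \*4, \*6, \*9, \*10, \*17,
\*29, \*34, \*35, \*39, \*41) using synthetic defining combinations in the
familiar structure, plus \*5, which as a whole-gene deletion has no
haplotype vector and enters only through the CNV channel. Its default
frequency vector (\*1 0.31, \*2 0.20, \*4 0.12, \*17 0.10, \*29 0.06,
\*41 0.06, \*10 0.05, \*35 0.03, \*39 0.02, \*9 0.02, \*3/\*6/\*34 0.01)
is typical of an admixed, partly African-ancestry population — the setting
where CYP2D6-activated drugs such as primaquine make phenotype prediction
most pressing.

What passing simulation tests do **not** show: robustness to genotyping
error, population stratification, linkage to off-panel markers, or allele
definitions diverging from the assayed population. The simulator models
missingness as the only assay imperfection.

## Benchmarks and problem sizes

The test suite and `scripts/acceptance.py` use cohort sizes chosen to make
each property measurable at interactive speed: grid-search cross-checks of
the EM optimum on 2-variant cohorts of ≤6 samples (full simplex grid at
step 1e-3 for ≤3 free dimensions, coarse-to-fine refinement to the same
final step above that); EM monotonicity over 100 seeded cohorts; end-to-end
recovery on 500 samples from the demo reference (≥95% diplotype and ≥97%
phenotype concordance with truth — these are this package's acceptance
settings for its own simulation conditions, not field error rates); and a
1300-sample batch for scale and byte-stability. On one CPU the whole suite
runs in seconds.

## Known limitations

* The HWE likelihood ignores linkage-disequilibrium structure beyond what
  haplotype frequencies capture; PHASE's coalescent prior can be better on
  small or sparse cohorts (import path provided).
* Joint phasing of a single sample is legal but uninformative (a warning is
  logged); posteriors then reflect only within-sample symmetry.
* Ambiguity-group and no-call handling is conservative by design; panels
  that cannot separate clinically distinct sub-alleles will produce joined
  names or indeterminate scores rather than guesses.
* Copy numbers are taken as given; the tool neither calls CNVs nor models
  CNV-assay uncertainty.
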