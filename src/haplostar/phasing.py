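"""Joint statistical haplotype phasing across a cohort.

The model is Hardy–Weinberg equilibrium: an individual's two haplotypes are
independent draws from a shared haplotype frequency vector ``p``.  The
likelihood of an unphased genotype ``g_i`` is

    P(g_i | p) = sum over compatible unordered pairs {k, l} of c_kl p_k p_l,

with ``c_kl = 2`` for heterozygous pairs (k != l) and ``1`` otherwise.
``p`` is estimated by maximum likelihood via EM over the whole cohort at
once — no external reference panel — and each individual is then assigned
the a-posteriori most probable haplotype pair together with its posterior
probability.  This mirrors population-based phasing as done by programs
such as PHASE, minus the approximate-coalescent prior: here the prior over
haplotypes is the estimated frequency vector itself.

Missing genotypes are handled by expanding the compatible-pair support over
the alleles observed at that site (cohort plus allele reference), the same
semantics as PHASE's ``?`` tokens, rather than imputing to a reference
allele.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ResolutionExplosionError, ValidationError
from .io import GenotypeRecord

#: A haplotype is an allele vector over the panel; tuples give value
#: hashing and a total (lexicographic) order for deterministic iteration.
Haplotype = tuple[str, ...]

#: Default cap on the resolution space: a sample may have at most
#: 2**DEFAULT_HET_CAP ordered phase configurations.  Effectively this allows
#: 15 heterozygous sites (targeted panels sit far below it).
DEFAULT_HET_CAP = 15

FLAG_TIE = "phase_tie"
FLAG_UNINFORMATIVE = "uninformative_phase"


@dataclass(frozen=True)
class PhasedPair:
    """A sample's most probable haplotype pair.

    ``posterior`` is the probability of this unordered pair among all pairs
    compatible with the genotype, under the estimated frequencies.  The pair
    is canonicalized so that ``h1 <= h2`` lexicographically.
    """

    sample_id: str
    h1: Haplotype
    h2: Haplotype
    posterior: float
    n_resolutions: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.h1 > self.h2:
            raise ValidationError("PhasedPair must be canonicalized (h1 <= h2)")


@dataclass
class HaplotypeFrequencySet:
    """Cohort-level ML haplotype frequencies with the EM convergence trace.

    ``freq`` maps each supported haplotype to its estimated probability
    (summing to 1); ``loglik_trace`` is the per-iteration log-likelihood of
    the best restart; ``restart_logliks`` records the converged
    log-likelihood of every restart.  ``wildcards`` are the per-site allele
    sets used to expand missing genotypes, kept so that subsequent phasing
    enumerates the identical support.
    """

    freq: dict[Haplotype, float]
    loglik_trace: list[float]
    restart_logliks: list[float] = field(default_factory=list)
    n_iterations: int = 0
    wildcards: tuple[frozenset[str], ...] | None = None

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


@dataclass(frozen=True)
class EMOptions:
    """Convergence and restart policy for the EM estimator."""

    tol: float = 1e-8
    max_iter: int = 1000
    n_restarts: int = 3
    seed: int = 0
    het_cap: int = DEFAULT_HET_CAP


def enumerate_resolutions(
    record: GenotypeRecord,
    wildcard_alleles: Sequence[Iterable[str]],
    het_cap: int = DEFAULT_HET_CAP,
) -> list[tuple[Haplotype, Haplotype]]:
    """All distinct unordered haplotype pairs compatible with a genotype.

    At a non-missing site the pair of haplotype alleles must equal the
    genotype pair (as multisets); at a missing site each haplotype may carry
    any allele from ``wildcard_alleles`` for that site.  With ``h``
    heterozygous sites and no missing data the count is ``max(1, 2**(h-1))``.

    Pairs are returned sorted, each canonicalized with ``h1 <= h2``.

    Raises
    ------
    ResolutionExplosionError
        If the ordered configuration space exceeds ``2**het_cap``.
    """
    options: list[list[tuple[str, str]]] = []
    total = 1
    for i, call in enumerate(record.calls):
        if call is None:
            alleles = sorted(set(wildcard_alleles[i]))
            if not alleles:
                raise ValidationError(
                    f"{record.sample_id}: no wildcard alleles for missing site {i}"
                )
            site = [(x, y) for x in alleles for y in alleles]
        elif call[0] == call[1]:
            site = [(call[0], call[1])]
        else:
            site = [(call[0], call[1]), (call[1], call[0])]
        options.append(site)
        total *= len(site)
        if total > 2**het_cap:
            raise ResolutionExplosionError(
                f"sample {record.sample_id!r}: more than 2^{het_cap} phase "
                "configurations (too many heterozygous/missing sites)"
            )

    seen: set[tuple[Haplotype, Haplotype]] = set()
    for combo in itertools.product(*options):
        h1 = tuple(x for x, _ in combo)
        h2 = tuple(y for _, y in combo)
        pair = (h1, h2) if h1 <= h2 else (h2, h1)
        seen.add(pair)
    return sorted(seen)


def _cohort_wildcards(
    records: Sequence[GenotypeRecord],
) -> tuple[frozenset[str], ...]:
    if not records:
        raise ValidationError("empty cohort")
    n = len(records[0].calls)
    sets: list[set[str]] = [set() for _ in range(n)]
    for rec in records:
        for i, call in enumerate(rec.calls):
            if call is not None:
                sets[i].update(call)
    return tuple(frozenset(s) for s in sets)


def _build_support(
    records: Sequence[GenotypeRecord],
    wildcards: Sequence[Iterable[str]],
    het_cap: int,
):
    """Index the union support and each sample's compatible pairs."""
    per_sample = [enumerate_resolutions(r, wildcards, het_cap) for r in records]
    support = sorted({h for pairs in per_sample for pair in pairs for h in pair})
    index = {h: k for k, h in enumerate(support)}
    ks, ls, cs, starts = [], [], [], []
    pos = 0
    for pairs in per_sample:
        starts.append(pos)
        for h1, h2 in pairs:
            ks.append(index[h1])
            ls.append(index[h2])
            cs.append(2.0 if h1 != h2 else 1.0)
        pos += len(pairs)
    return (
        support,
        per_sample,
        np.asarray(ks, dtype=np.intp),
        np.asarray(ls, dtype=np.intp),
        np.asarray(cs, dtype=np.float64),
        np.asarray(starts, dtype=np.intp),
    )


def _run_em(
    p0: np.ndarray,
    ks: np.ndarray,
    ls: np.ndarray,
    cs: np.ndarray,
    starts: np.ndarray,
    sample_of_pair: np.ndarray,
    n_samples: int,
    n_hap: int,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, list[float], int]:
    p = p0.copy()
    trace: list[float] = []
    for it in range(max_iter):
        w = cs * p[ks] * p[ls]
        tot = np.add.reduceat(w, starts)
        tot_safe = np.maximum(tot, 1e-300)
        ll = float(np.log(tot_safe).sum())
        trace.append(ll)
        post = w / tot_safe[sample_of_pair]
        counts = np.bincount(ks, weights=post, minlength=n_hap) + np.bincount(
            ls, weights=post, minlength=n_hap
        )
        p = counts / (2.0 * n_samples)
        if it > 0 and abs(trace[-1] - trace[-2]) < tol:
            break
    # record the likelihood of the final parameter vector
    w = cs * p[ks] * p[ls]
    tot = np.maximum(np.add.reduceat(w, starts), 1e-300)
    trace.append(float(np.log(tot).sum()))
    return p, trace, len(trace)


def em_estimate(
    records: Sequence[GenotypeRecord],
    opts: EMOptions | None = None,
    wildcards: Sequence[Iterable[str]] | None = None,
) -> HaplotypeFrequencySet:
    """Maximum-likelihood haplotype frequencies under Hardy–Weinberg via EM.

    E-step: per sample, the posterior of each compatible pair ``{k, l}`` is
    ``c_kl p_k p_l`` normalized over the sample's pairs.  M-step: ``p_k``
    is the expected count of haplotype ``k`` over ``2N`` chromosomes.
    Iterates until the log-likelihood changes by less than ``opts.tol`` or
    ``opts.max_iter`` is reached; the best of ``opts.n_restarts`` restarts
    is kept (restart 0 starts uniform; later restarts perturb the start
    point with seeded Dirichlet draws to escape symmetric saddle points).

    Parameters
    ----------
    records
        The cohort; phasing is joint, so this is the whole dataset.
    opts
        Convergence/restart policy; defaults to :class:`EMOptions`.
    wildcards
        Per-site allele sets used to expand missing genotypes.  Defaults to
        the alleles observed in the cohort itself; pipelines pass the union
        with the allele-reference alleles.
    """
    if not records:
        raise ValidationError("empty cohort")
    opts = opts or EMOptions()
    wc = tuple(
        frozenset(s) for s in (wildcards if wildcards is not None else _cohort_wildcards(records))
    )
    support, per_sample, ks, ls, cs, starts = _build_support(records, wc, opts.het_cap)
    n_hap = len(support)
    n_samples = len(records)
    sample_of_pair = np.repeat(
        np.arange(n_samples), [len(p) for p in per_sample]
    )

    rng = np.random.default_rng(opts.seed)
    best: tuple[np.ndarray, list[float], int] | None = None
    restart_lls: list[float] = []
    for r in range(max(1, opts.n_restarts)):
        if r == 0:
            p0 = np.full(n_hap, 1.0 / n_hap)
        else:
            p0 = rng.dirichlet(np.ones(n_hap))
        p, trace, n_it = _run_em(
            p0, ks, ls, cs, starts, sample_of_pair, n_samples, n_hap,
            opts.tol, opts.max_iter,
        )
        restart_lls.append(trace[-1])
        if best is None or trace[-1] > best[1][-1]:
            best = (p, trace, n_it)

    assert best is not None
    p, trace, n_it = best
    p = np.maximum(p, 0.0)
    p = p / p.sum()
    return HaplotypeFrequencySet(
        freq={h: float(p[k]) for k, h in enumerate(support)},
        loglik_trace=trace,
        restart_logliks=restart_lls,
        n_iterations=n_it,
        wildcards=wc,
    )


def phase_cohort(
    records: Sequence[GenotypeRecord],
    freqs: HaplotypeFrequencySet,
    het_cap: int = DEFAULT_HET_CAP,
) -> list[PhasedPair]:
    """Assign each sample its most probable haplotype pair under ``freqs``.

    The posterior of the reported pair is its normalized Hardy–Weinberg
    probability among all compatible pairs.  Exact ties resolve to the
    lexicographically smallest pair with a ``phase_tie`` flag.  A sample
    whose every compatible pair has zero estimated frequency mass gets a
    uniform posterior over its resolutions and an ``uninformative_phase``
    flag.
    """
    if freqs.wildcards is not None:
        wc: Sequence[Iterable[str]] = freqs.wildcards
    else:
        wc = _cohort_wildcards(records)
    out: list[PhasedPair] = []
    for rec in records:
        pairs = enumerate_resolutions(rec, wc, het_cap)
        probs = np.array(
            [
                (2.0 if h1 != h2 else 1.0)
                * freqs.freq.get(h1, 0.0)
                * freqs.freq.get(h2, 0.0)
                for h1, h2 in pairs
            ]
        )
        tot = probs.sum()
        flags: list[str] = []
        if tot <= 0.0:
            idx = 0  # pairs are sorted: lexicographically smallest
            posterior = 1.0 / len(pairs)
            flags.append(FLAG_UNINFORMATIVE)
        else:
            norm = probs / tot
            best_p = norm.max()
            tied = np.flatnonzero(norm >= best_p * (1.0 - 1e-9))
            idx = int(tied[0])
            posterior = float(norm[idx])
            if len(tied) > 1:
                flags.append(FLAG_TIE)
        h1, h2 = pairs[idx]
        out.append(
            PhasedPair(
                sample_id=rec.sample_id,
                h1=h1,
                h2=h2,
                posterior=float(posterior),
                n_resolutions=len(pairs),
                flags=tuple(flags),
            )
        )
    return out
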