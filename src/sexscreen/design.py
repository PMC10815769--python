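"""Sampling-design error models for pseudo sex-specific markers.

When a group of n females and n males of a diploid species is screened for
sex-specific sequence, an autosomal presence/absence locus can mimic perfect
sex linkage: under a ZW system every sampled female happens to be
heterozygous Aa while every sampled male is homozygous, and the insertion
allele then segregates exactly with sex in the sample.  For a locus with
allele frequencies p and q = 1 - p in Hardy-Weinberg proportions the
probability of that coincidence in one sampled group is

    P_E(single system) = (pq)^n * [(p^2/2)^n + (q^2/2)^n]

(the heterogametic sex is Aa with probability pq per the sampling table used
here; each homogamete is the matching homozygote, halved for the two equally
likely sex assignments of the homozygote class), and twice that when both ZW
and XY explanations are admitted.  Sequencing a single-sex pool of N extra
homogametic individuals multiplies the term for homozygote class with allele
frequency r by r^(2N): every pooled individual must also be that homozygote
or the pool's reads disprove the marker.

Monte-Carlo summaries over p ~ Uniform(0, 1) drive the sample-size
recommendation (at least 3 + 3 individuals and a pool of ~15 in the
motivating study).  The exact uniform-p mean of the combined-system rate is
available in closed form, ``2^(2-n) * B(3n+1, n+1)``, and serves as the
oracle for the simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import betaln

System = Literal["ZW", "XY", "combined"]
RPolicy = Literal["literal_choice", "matched", "independent_per_individual"]

R_POLICIES = ("literal_choice", "matched", "independent_per_individual")


@dataclass(frozen=True)
class PopulationModel:
    """Hardy-Weinberg frequencies of one biallelic autosomal locus."""

    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"allele frequency p must be in [0, 1], got {self.p}")

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def genotype_freqs(self) -> tuple[float, float, float]:
        """(AA, Aa, aa) = (p^2, 2pq, q^2)."""
        p, q = self.p, self.q
        return (p * p, 2.0 * p * q, q * q)


@dataclass(frozen=True)
class RateSummary:
    """Moments of a sampled error-rate distribution."""

    mean: float
    median: float
    min: float
    max: float
    std: float


@dataclass(frozen=True)
class DesignSummary:
    group_size: int
    system: str
    iterations: int
    seed: int
    rates: RateSummary

    @property
    def sem(self) -> float:
        return self.rates.std / math.sqrt(self.iterations)


@dataclass(frozen=True)
class PoolDesignSummary:
    pool_size: int
    group_size: int
    r_policy: str
    iterations: int
    seed: int
    rates: RateSummary

    @property
    def sem(self) -> float:
        return self.rates.std / math.sqrt(self.iterations)


@dataclass(frozen=True)
class DesignRecommendation:
    """Smallest sample sizes meeting the requested error-rate thresholds."""

    group_size: int | None
    pool_size: int | None
    statistic: str
    r_policy: str
    rate_threshold_group: float
    rate_threshold_pool: float
    searched_group_sizes: tuple[int, ...] = field(default=())
    searched_pool_sizes: tuple[int, ...] = field(default=())

    @property
    def group_reached(self) -> bool:
        return self.group_size is not None

    @property
    def pool_reached(self) -> bool:
        return self.pool_size is not None


def _check_n(n: int) -> None:
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"group size n must be an integer >= 1, got {n!r}")


def pseudo_marker_rate(p, n: int, system: System = "combined"):
    """Probability that an autosomal HWE locus mimics sex linkage.

    Accepts a scalar or array of allele frequencies.  ``system`` selects the
    single-system expression (``"ZW"``/``"XY"``, which are symbolic mirrors
    of each other) or the combined expression (doubled, admitting either
    heterogametic explanation).
    """
    _check_n(n)
    if system not in ("ZW", "XY", "combined"):
        raise ValueError(f"unknown system {system!r}")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("allele frequency p must be in [0, 1]")
    q = 1.0 - p_arr
    pq = p_arr * q
    rate = pq**n * ((p_arr**2 / 2.0) ** n + (q**2 / 2.0) ** n)
    if system == "combined":
        rate = 2.0 * rate
    return rate if isinstance(rate, np.ndarray) and rate.ndim else float(rate)


def expected_rate_closed_form(n: int, system: System = "combined") -> float:
    """Exact mean of :func:`pseudo_marker_rate` under p ~ Uniform(0, 1).

    The combined-system mean is ``2^(2-n) * B(3n+1, n+1)`` with B the Beta
    function; the single-system mean is half that.
    """
    _check_n(n)
    mean = math.exp((2 - n) * math.log(2.0) + betaln(3 * n + 1, n + 1))
    if system != "combined":
        mean /= 2.0
    return mean


def pool_error_rate(p, r, n: int, N: int, system: System = "ZW"):
    """Pseudo-marker rate after sequencing a single-sex pool of N individuals.

    ``r`` may be

    * a scalar: both homozygote terms are multiplied by ``r**(2N)``;
    * a pair ``(r_AA, r_aa)``: term-wise factors (the "matched" reading,
      where the pool must repeat each term's homozygote class);
    * a sequence of N per-individual frequencies: both terms are multiplied
      by ``prod(r_i**2)``.

    ``N = 0`` reduces exactly to the single-system :func:`pseudo_marker_rate`.
    """
    _check_n(n)
    if not (isinstance(N, (int, np.integer)) and N >= 0):
        raise ValueError(f"pool size N must be an integer >= 0, got {N!r}")
    if system not in ("ZW", "XY"):
        raise ValueError("pool model applies to a known single system (ZW or XY)")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("allele frequency p must be in [0, 1]")
    q = 1.0 - p_arr
    pq = p_arr * q
    term_AA = pq**n * (p_arr**2 / 2.0) ** n
    term_aa = pq**n * (q**2 / 2.0) ** n

    if np.ndim(r) == 0:
        r_val = float(r)
        if not 0.0 <= r_val <= 1.0:
            raise ValueError("r must be in [0, 1]")
        factor = r_val ** (2 * N)
        rate = (term_AA + term_aa) * factor
    elif isinstance(r, tuple) and len(r) == 2:
        r_AA, r_aa = (np.asarray(x, dtype=float) for x in r)
        rate = term_AA * r_AA ** (2 * N) + term_aa * r_aa ** (2 * N)
    else:
        r_arr = np.asarray(r, dtype=float)
        if r_arr.shape[-1] != N:
            raise ValueError(f"expected {N} per-individual r values, got {r_arr.shape}")
        if np.any((r_arr < 0) | (r_arr > 1)):
            raise ValueError("r must be in [0, 1]")
        factor = np.prod(r_arr**2, axis=-1)
        rate = (term_AA + term_aa) * factor
    return rate if isinstance(rate, np.ndarray) and rate.ndim else float(rate)


def _summary(rates: np.ndarray) -> RateSummary:
    return RateSummary(
        mean=float(rates.mean()),
        median=float(np.median(rates)),
        min=float(rates.min()),
        max=float(rates.max()),
        std=float(rates.std(ddof=1)),
    )


def _rng_for(seed: int, n: int) -> np.random.Generator:
    # keyed by (seed, group size) so a given n reproduces independently of
    # list position, and the pool simulator can share the same p stream
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(n)]))


def simulate_design(
    group_sizes: Sequence[int],
    iterations: int = 1_000_000,
    seed: int = 0,
    system: System = "combined",
) -> list[DesignSummary]:
    """Monte-Carlo distribution of P_E over p ~ Uniform(0, 1) per group size."""
    if not group_sizes:
        raise ValueError("group_sizes must be non-empty")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    out = []
    for n in group_sizes:
        _check_n(n)
        rng = _rng_for(seed, n)
        p = rng.uniform(size=iterations)
        rates = pseudo_marker_rate(p, n, system)
        out.append(
            DesignSummary(
                group_size=int(n),
                system=system,
                iterations=int(iterations),
                seed=int(seed),
                rates=_summary(np.asarray(rates)),
            )
        )
    return out


def _pool_rates(
    p: np.ndarray,
    pool_sizes: Sequence[int],
    n: int,
    r_policy: str,
    rng: np.random.Generator,
    system: System,
) -> dict[int, np.ndarray]:
    """Per-N rate arrays from one shared set of draws (monotone in N)."""
    q = 1.0 - p
    pq = p * q
    term_AA = pq**n * (p**2 / 2.0) ** n
    term_aa = pq**n * (q**2 / 2.0) ** n
    n_max = max(pool_sizes)
    rates: dict[int, np.ndarray] = {}
    if r_policy == "literal_choice":
        # r is set to p or q with equal probability, one draw per iteration
        r = np.where(rng.random(p.size) < 0.5, p, q)
        for N in pool_sizes:
            rates[N] = (term_AA + term_aa) * r ** (2 * N)
    elif r_policy == "matched":
        # each term's pool must repeat that term's homozygote class
        for N in pool_sizes:
            rates[N] = term_AA * p ** (2 * N) + term_aa * q ** (2 * N)
    elif r_policy == "independent_per_individual":
        # fresh Uniform(0,1) frequency per pool member; E[r^2] = 1/3
        if n_max > 0:
            r = rng.random((p.size, n_max))
            cum = np.cumprod(r**2, axis=1)
        for N in pool_sizes:
            factor = 1.0 if N == 0 else cum[:, N - 1]
            rates[N] = (term_AA + term_aa) * factor
    else:
        raise ValueError(f"unknown r policy {r_policy!r}; choose from {R_POLICIES}")
    return rates


def simulate_pool_design(
    pool_sizes: Sequence[int],
    n: int = 3,
    r_policy: RPolicy = "literal_choice",
    iterations: int = 1_000_000,
    seed: int = 0,
    system: System = "ZW",
) -> list[PoolDesignSummary]:
    """Monte-Carlo distribution of P_E-Pool per pool size N.

    All pool sizes are evaluated on one shared set of (p, r) draws, so the
    sampled rates are element-wise non-increasing in N and the N = 0 entry
    reproduces the single-system group simulation for the same seed.
    """
    if not pool_sizes:
        raise ValueError("pool_sizes must be non-empty")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    _check_n(n)
    if any((not isinstance(N, (int, np.integer))) or N < 0 for N in pool_sizes):
        raise ValueError("pool sizes must be integers >= 0")
    if system not in ("ZW", "XY"):
        raise ValueError("pool model applies to a known single system (ZW or XY)")
    rng = _rng_for(seed, n)
    p = rng.uniform(size=iterations)  # identical to simulate_design's stream
    rates = _pool_rates(p, list(pool_sizes), n, r_policy, rng, system)
    return [
        PoolDesignSummary(
            pool_size=int(N),
            group_size=int(n),
            r_policy=r_policy,
            iterations=int(iterations),
            seed=int(seed),
            rates=_summary(rates[N]),
        )
        for N in pool_sizes
    ]


def recommend_design(
    rate_threshold_group: float = 1e-3,
    rate_threshold_pool: float = 1e-10,
    statistic: Literal["mean", "max"] = "mean",
    r_policy: RPolicy = "independent_per_individual",
    group_sizes: Sequence[int] = tuple(range(1, 11)),
    pool_sizes: Sequence[int] = tuple(range(0, 31)),
    iterations: int = 1_000_000,
    seed: int = 0,
) -> DesignRecommendation:
    """Smallest group size n and pool size N meeting the rate thresholds.

    The pool search is run at the recommended group size (or the largest
    searched n if the group threshold is never reached).  An unreachable
    threshold yields ``None`` for that size rather than an exception.
    """
    for thr in (rate_threshold_group, rate_threshold_pool):
        if not 0.0 < thr < 1.0:
            raise ValueError("thresholds must lie in (0, 1)")
    if statistic not in ("mean", "max"):
        raise ValueError("statistic must be 'mean' or 'max'")

    n_star: int | None = None
    for summ in simulate_design(group_sizes, iterations, seed):
        if getattr(summ.rates, statistic) < rate_threshold_group:
            n_star = summ.group_size
            break

    n_for_pool = n_star if n_star is not None else max(group_sizes)
    N_star: int | None = None
    for summ in simulate_pool_design(pool_sizes, n_for_pool, r_policy, iterations, seed):
        if getattr(summ.rates, statistic) < rate_threshold_pool:
            N_star = summ.pool_size
            break

    return DesignRecommendation(
        group_size=n_star,
        pool_size=N_star,
        statistic=statistic,
        r_policy=r_policy,
        rate_threshold_group=rate_threshold_group,
        rate_threshold_pool=rate_threshold_pool,
        searched_group_sizes=tuple(int(n) for n in group_sizes),
        searched_pool_sizes=tuple(int(N) for N in pool_sizes),
    )
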