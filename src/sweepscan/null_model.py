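"""Resampled null distributions and tail percentiles.

The neutral baseline for a window statistic at size n is built by
unrestricted random sampling: each of r draws picks n loci independently and
uniformly WITH replacement from the pool (one chromosome by default, or the
whole genome), ignoring chromosomal adjacency, and computes the statistic
with exactly the same formula as the observed windows. An observed value is
then ranked inside the sorted resample: the lower-tail percentile is the
inclusive rank count(null <= observed)/r, the upper tail count(null >=
observed)/r. Values more extreme than every resampled draw are floored at
1/(r+1) — the resolution limit of r — so the -log10 transform stays finite.

A z-score alternative converts the observed value to a normal tail
probability using the null's mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal
import warnings

import numpy as np
from scipy import stats as sps

from .allele_data import LocusTable
from .window_stats import _check_size

Tail = Literal["lower", "upper"]

#: statistic id -> (source column template, reduction)
#: mean_het{j} averages population j's heterozygosity; mean_fst averages
#: F_ST; s2_fst is the variance of F_ST within the draw/window.
MEAN_STATS = ("mean_het", "mean_fst")

RECOMMENDED_MIN_RESAMPLES = 1000


def statistic_column(statistic: str) -> str:
    """Map a statistic id to the locus-table column it draws from."""
    if statistic.startswith("mean_het"):
        j = statistic[len("mean_het"):]
        if not j.isdigit() or int(j) < 1:
            raise ValueError(f"bad heterozygosity statistic id {statistic!r}")
        return f"het{j}"
    if statistic in ("mean_fst", "s2_fst"):
        return "fst"
    raise ValueError(f"unknown statistic {statistic!r}")


def statistic_kind(statistic: str) -> str:
    return "var" if statistic == "s2_fst" else "mean"


@dataclass(frozen=True)
class TailPercentile:
    """A tail percentile in (0, 1] with its -log10 transform. ``degenerate``
    marks a zero-variance null (a constant statistic carries no signal)."""

    value: float
    tail: Tail
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.value <= 1.0):
            raise ValueError(f"percentile must be in (0, 1], got {self.value}")

    @property
    def neglog10(self) -> float:
        return float(np.log10(1.0 / self.value))


@dataclass
class NullDistribution:
    """Sorted resampled values of one statistic at one window size."""

    statistic: str
    window_size: int
    values: np.ndarray
    r: int
    seed: int | None
    pool_scope: str = "chromosome"

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if len(self.values) != self.r:
            raise ValueError("NullDistribution length must equal r")
        if self.r < RECOMMENDED_MIN_RESAMPLES:
            warnings.warn(
                f"r={self.r} resamples is below the recommended minimum of "
                f"{RECOMMENDED_MIN_RESAMPLES}; percentiles will be coarse",
                stacklevel=2,
            )

    @property
    def floor(self) -> float:
        return 1.0 / (self.r + 1)


def resample_statistic(
    pool: np.ndarray,
    size: int,
    kind: str,
    r: int,
    rng: np.random.Generator,
    ddof: int = 1,
    chunk: int = 200_000,
) -> np.ndarray:
    """r draws of `size` values with replacement from `pool`, reduced by
    mean or var — the statistic formula shared with the observed windows."""
    pool = np.asarray(pool, dtype=float)
    out = np.empty(r)
    # chunked so r up to ~1e7 stays within memory
    for start in range(0, r, chunk):
        stop = min(start + chunk, r)
        idx = rng.integers(0, len(pool), size=(stop - start, size))
        draws = pool[idx]
        if kind == "mean":
            out[start:stop] = draws.mean(axis=1)
        else:
            out[start:stop] = draws.var(axis=1, ddof=ddof)
    return out


def build_null(
    table: LocusTable,
    size: int,
    statistic: str,
    r: int,
    seed: int | None = 0,
    pool_scope: str = "chromosome",
    chrom: str | None = None,
    ddof: int = 1,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Build the resampled baseline for ``statistic`` at window size ``size``.

    ``pool_scope="chromosome"`` (default) draws loci from ``chrom`` only —
    random locations along the chromosome; ``"genome"`` pools all loci.
    Pass ``rng`` to stream draws from an existing generator (used by the
    scan so the draw order is documented and reproducible); otherwise a
    fresh generator is seeded with ``seed``.
    """
    _check_size(size)
    if r < 1:
        raise ValueError("r must be >= 1")
    if pool_scope not in ("chromosome", "genome"):
        raise ValueError("pool_scope must be 'chromosome' or 'genome'")
    col = statistic_column(statistic)
    if pool_scope == "chromosome":
        if chrom is None:
            chroms = table.chromosomes()
            if len(chroms) != 1:
                raise ValueError("chrom is required with pool_scope='chromosome'")
            chrom = chroms[0]
        pool = table.chromosome(chrom)[col].to_numpy(float)
    else:
        pool = table.df[col].to_numpy(float)
    if len(pool) < size:
        raise ValueError(
            f"pool of {len(pool)} loci is smaller than window size {size}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    values = resample_statistic(pool, size, statistic_kind(statistic), r, rng, ddof=ddof)
    return NullDistribution(
        statistic=statistic, window_size=size, values=values, r=r,
        seed=seed, pool_scope=pool_scope,
    )


def percentile_values(null: NullDistribution, observed, tail: Tail) -> np.ndarray:
    """Vectorised inclusive-rank tail percentiles, floored at 1/(r+1)."""
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    if tail == "lower":
        rank = np.searchsorted(null.values, obs, side="right")
    elif tail == "upper":
        rank = null.r - np.searchsorted(null.values, obs, side="left")
    else:
        raise ValueError("tail must be 'lower' or 'upper'")
    return np.maximum(rank / null.r, null.floor)


def percentile(null: NullDistribution, observed: float, tail: Tail) -> TailPercentile:
    """Tail percentile of one observed value within the resampled baseline:
    the inclusive rank (count of resampled values at least as un-extreme,
    ties included) divided by r, floored at 1/(r+1)."""
    p = float(percentile_values(null, observed, tail)[0])
    return TailPercentile(value=p, tail=tail)


def zscore_probability(null: NullDistribution, observed: float, tail: Tail) -> TailPercentile:
    """Normal tail probability of the observed value under the null's mean
    and standard deviation; the z-score alternative to rank percentiles."""
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    mu = float(null.values.mean())
    sd = float(null.values.std(ddof=1)) if null.r > 1 else 0.0
    if _degenerate(mu, sd):
        return TailPercentile(value=1.0, tail=tail, degenerate=True)
    z = (observed - mu) / sd
    p = sps.norm.sf(z) if tail == "upper" else sps.norm.cdf(z)
    return TailPercentile(value=float(max(p, null.floor)), tail=tail)


def _degenerate(mu: float, sd: float) -> bool:
    # constant statistic up to float rounding of the accumulated mean
    return sd <= 1e-12 * max(1.0, abs(mu))


def zscore_values(null: NullDistribution, observed, tail: Tail) -> np.ndarray:
    """Vectorised z-score tail probabilities (degenerate null -> all 1)."""
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    mu = float(null.values.mean())
    sd = float(null.values.std(ddof=1)) if null.r > 1 else 0.0
    if _degenerate(mu, sd):
        return np.ones_like(obs)
    z = (obs - mu) / sd
    p = sps.norm.sf(z) if tail == "upper" else sps.norm.cdf(z)
    return np.maximum(p, null.floor)
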