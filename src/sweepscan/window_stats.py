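"""Sliding-window statistics over consecutive loci.

Windows are defined in locus-index space: a window of size n (odd, >= 5)
covers n consecutive records of one chromosome, centered on every SNP whose
flanks fit. Windows never span chromosome boundaries and are never padded.
Per window we report the mean heterozygosity of each population, the mean
F_ST, and the multi-locus F_ST variance (S2_FST) — the variance of the
per-locus F_ST values inside the window, which captures the alternation of
high and low F_ST produced by differing swept haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .allele_data import LocusTable

MIN_WINDOW = 5


def _check_size(size: int) -> None:
    if size < MIN_WINDOW or size % 2 == 0:
        raise ValueError(f"window size must be odd and >= {MIN_WINDOW}, got {size}")


@dataclass(frozen=True)
class WindowSpec:
    """A window of ``size`` loci centered at ``center_index`` (index within
    the chromosome's record list, not a base-pair coordinate)."""

    chrom: str
    center_index: int
    size: int

    def __post_init__(self) -> None:
        _check_size(self.size)
        if self.center_index < (self.size - 1) // 2:
            raise ValueError("window extends past the chromosome start")


@dataclass(frozen=True)
class WindowStats:
    spec: WindowSpec
    mean_het: tuple[float, ...]
    mean_fst: float
    s2_fst: float


def default_window_sizes(min_size: int = 5, max_size: int = 65, step: int = 2) -> list[int]:
    """The default grid of window sizes: 5, 7, ..., 65 (31 sizes)."""
    if min_size % 2 == 0 or max_size % 2 == 0:
        raise ValueError("window sizes must be odd")
    if step <= 0 or step % 2 != 0:
        raise ValueError("step must be a positive even integer")
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    return list(range(min_size, max_size + 1, step))


def iter_windows(table: LocusTable, size: int):
    """Yield every :class:`WindowSpec` of ``size`` loci that fits fully
    inside a chromosome, for all chromosomes in order. A chromosome with
    fewer than ``size`` loci yields nothing."""
    _check_size(size)
    half = (size - 1) // 2
    for chrom in table.chromosomes():
        n = len(table.chromosome(chrom))
        for center in range(half, n - half):
            yield WindowSpec(chrom=chrom, center_index=center, size=size)


def window_summary(table: LocusTable, spec: WindowSpec, ddof: int = 1) -> WindowStats:
    """Compute one window's mean heterozygosities, mean F_ST and S2_FST.

    ``ddof=1`` gives the sample variance (default); ``ddof=0`` the population
    variance. Percentile ranks downstream are invariant to this choice as
    long as observed and resampled statistics share it — they do, by
    construction (:func:`sliding_stat` and the null builder call the same
    numpy reductions with the same ``ddof``).
    """
    sub = table.chromosome(spec.chrom)
    half = (spec.size - 1) // 2
    lo, hi = spec.center_index - half, spec.center_index + half + 1
    if lo < 0 or hi > len(sub):
        raise ValueError(f"{spec} does not fit chromosome {spec.chrom} ({len(sub)} loci)")
    block = sub.iloc[lo:hi]
    het = tuple(float(block[c].mean()) for c in table.het_cols)
    fst = block["fst"].to_numpy(float)
    return WindowStats(
        spec=spec,
        mean_het=het,
        mean_fst=float(fst.mean()),
        s2_fst=float(fst.var(ddof=ddof)),
    )


def sliding_stat(values: np.ndarray, size: int, kind: str, ddof: int = 1) -> np.ndarray:
    """Vectorised per-window statistic over one chromosome's locus values.

    Returns one value per fitting window, in center-index order (centers
    (size-1)/2 .. L-1-(size-1)/2). ``kind`` is ``"mean"`` or ``"var"``.
    """
    _check_size(size)
    values = np.asarray(values, dtype=float)
    if len(values) < size:
        return np.empty(0)
    windows = sliding_window_view(values, size)
    if kind == "mean":
        return windows.mean(axis=1)
    if kind == "var":
        return windows.var(axis=1, ddof=ddof)
    raise ValueError(f"unknown statistic kind {kind!r}")
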