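"""The genome scan: window statistics vs resampled nulls, per-locus extremes.

For every chromosome and every window size in the grid (default 5..65 by 2),
the scan builds one resampled null per statistic, scores every fitting
window, and assigns the tail percentile to the window's central locus. Per
locus and statistic the smallest percentile across window sizes is kept
(ties broken toward the smaller window, for sharper localization), together
with the window size and the raw window statistic that achieved it.

Tails are fixed by the selection model: mean heterozygosity is tested in the
lower tail (a sweep depresses diversity), mean F_ST and the F_ST variance
S2_FST in the upper tail (differentiation and its alternation rise after a
post-split sweep).

Each locus is then classified into one of four outcomes:

* ``none`` — no statistic extreme at alpha (does not exclude selection);
* ``old_selection`` — heterozygosity extreme-low in every population with
  F_ST statistics at background: a sweep predating the population split;
* ``new_selection_one_pop`` — exactly one population's heterozygosity
  extreme-low and S2_FST extreme-high: a sweep in one derived population;
* ``new_selection_both`` — all heterozygosities extreme-low and S2_FST
  extreme-high: post-split sweeps in both populations.

Classification uses heterozygosity and S2_FST; mean F_ST percentiles are
reported but F_ST alone is a weak indicator and only vetoes the old-selection
call. The scan is a candidate-discovery tool: extreme percentiles nominate
regions for downstream validation, they do not prove selection.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .allele_data import LocusTable, ParseError, _is_number
from .null_model import (
    NullDistribution,
    build_null,
    percentile_values,
    statistic_column,
    statistic_kind,
    zscore_values,
)
from .window_stats import default_window_sizes, sliding_stat

logger = logging.getLogger(__name__)

OUTCOMES = ("none", "old_selection", "new_selection_one_pop", "new_selection_both")
UNEVALUATED = "unevaluated"


def statistic_ids(n_pops: int) -> list[str]:
    return [f"mean_het{j + 1}" for j in range(n_pops)] + ["mean_fst", "s2_fst"]


def statistic_tail(statistic: str) -> str:
    """Lower tail for heterozygosity (sweeps depress it), upper for the
    F_ST statistics (post-split sweeps inflate them)."""
    return "lower" if statistic.startswith("mean_het") else "upper"


@dataclass
class ScanConfig:
    """Scan parameters.

    window_sizes: odd, ascending; default 5..65 step 2 (31 sizes).
    r: resamples per null (default 1e5; >= 1000 recommended — percentile
       resolution is 1/(r+1)).
    pool_scope: 'chromosome' (default) or 'genome' null pools.
    method: 'percentile' (rank in the resample) or 'zscore'.
    alpha: classification threshold on the best percentiles (default 0.01).
    ddof: variance denominator for S2_FST (1 = sample variance).
    min_genotypes: converter filter carried in the config for provenance.
    """

    window_sizes: tuple[int, ...] = tuple(default_window_sizes())
    r: int = 100_000
    seed: int = 0
    pool_scope: str = "chromosome"
    method: str = "percentile"
    alpha: float = 0.01
    ddof: int = 1
    min_genotypes: int = 10

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.window_sizes)
        if not sizes or any(s % 2 == 0 or s < 5 for s in sizes):
            raise ValueError("window sizes must be odd integers >= 5")
        if list(sizes) != sorted(sizes):
            raise ValueError("window sizes must be ascending")
        self.window_sizes = sizes
        if self.method not in ("percentile", "zscore"):
            raise ValueError("method must be 'percentile' or 'zscore'")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.r < 1:
            raise ValueError("r must be >= 1")


def neglog10(p: float):
    """-log10 transform of a percentile: log10(1/p). Defined on (0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("percentile must be in (0, 1]")
    out = np.log10(1.0 / arr)
    return float(out) if out.ndim == 0 else out


def classify_pattern(
    p_het: Sequence[float],
    p_s2_fst: float,
    p_mean_fst: float = 1.0,
    alpha: float = 0.01,
) -> str:
    """Classify one locus's best percentiles into the four outcomes.

    ``p_het`` holds the per-population best lower-tail heterozygosity
    percentiles; ``p_s2_fst`` and ``p_mean_fst`` the best upper-tail F_ST
    percentiles. Any missing (NaN) value marks the locus unevaluated.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    vals = list(p_het) + [p_s2_fst, p_mean_fst]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        return UNEVALUATED
    het_low = [p < alpha for p in p_het]
    s2_high = p_s2_fst < alpha
    fst_high = p_mean_fst < alpha
    if all(het_low) and s2_high:
        return "new_selection_both"
    if sum(het_low) == 1 and s2_high:
        return "new_selection_one_pop"
    if all(het_low) and not s2_high and not fst_high:
        return "old_selection"
    return "none"


def run_scan(table: LocusTable, config: ScanConfig | None = None) -> pd.DataFrame:
    """Run the full scan and return one row per locus.

    Columns: ``name, chrom, pos, n_sizes`` then per statistic ``{stat}_p``
    (best percentile across window sizes), ``{stat}_size`` (achieving window
    size), ``{stat}_value`` (the raw window statistic at that size),
    ``{stat}_neglog10``, and finally ``outcome``. Loci with no fitting window
    at any size carry NaN percentiles and outcome ``unevaluated``.

    One null per (chromosome pool, statistic, window size) is built and
    reused for every window of that size; draws stream from a single seeded
    generator in chromosome x statistic x size x draw order, so runs are
    reproducible bit-for-bit given the config.
    """
    if config is None:
        config = ScanConfig()
    stats = statistic_ids(table.n_pops)
    n = len(table)
    if n == 0:
        warnings.warn("empty locus table; nothing to scan")
        return _empty_result(stats)

    best_p = {s: np.full(n, np.inf) for s in stats}
    best_size = {s: np.zeros(n, dtype=int) for s in stats}
    best_val = {s: np.full(n, np.nan) for s in stats}
    n_sizes = np.zeros(n, dtype=int)

    rng = np.random.default_rng(config.seed)
    min_size = config.window_sizes[0]
    any_chrom = False

    if config.pool_scope == "genome":
        genome_nulls: dict[tuple[str, int], NullDistribution] = {}

    for chrom in table.chromosomes():
        mask = (table.df["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        L = len(idx)
        if L < min_size:
            logger.info("chromosome %s has %d loci (< %d); skipped", chrom, L, min_size)
            continue
        any_chrom = True
        cols = {s: table.df.loc[mask, statistic_column(s)].to_numpy(float) for s in stats}
        for statistic in stats:
            tail = statistic_tail(statistic)
            values = cols[statistic]
            for size in config.window_sizes:
                if L < size:
                    break  # sizes ascending: nothing larger fits either
                if config.pool_scope == "genome":
                    key = (statistic, size)
                    if key not in genome_nulls:
                        genome_nulls[key] = build_null(
                            table, size, statistic, config.r,
                            pool_scope="genome", ddof=config.ddof, rng=rng,
                            seed=config.seed,
                        )
                    null = genome_nulls[key]
                else:
                    null = build_null(
                        table, size, statistic, config.r, pool_scope="chromosome",
                        chrom=chrom, ddof=config.ddof, rng=rng, seed=config.seed,
                    )
                obs = sliding_stat(values, size, statistic_kind(statistic), ddof=config.ddof)
                if config.method == "percentile":
                    p = percentile_values(null, obs, tail)
                else:
                    p = zscore_values(null, obs, tail)
                half = (size - 1) // 2
                centers = idx[half : L - half]
                better = p < best_p[statistic][centers]  # strict: ties keep smaller size
                upd = centers[better]
                best_p[statistic][upd] = p[better]
                best_size[statistic][upd] = size
                best_val[statistic][upd] = obs[better]
        # number of window sizes evaluated depends only on edge distance
        offset = np.arange(L)
        room = np.minimum(offset, L - 1 - offset)  # flank that fits
        fits = np.array(config.window_sizes)[None, :] <= (2 * room[:, None] + 1)
        n_sizes[idx] = fits.sum(axis=1)

    if not any_chrom:
        warnings.warn("no chromosome has enough loci for the smallest window")

    out = table.df[["name", "chrom", "pos"]].copy()
    out["n_sizes"] = n_sizes
    evaluated = n_sizes > 0
    for s in stats:
        p = np.where(evaluated, best_p[s], np.nan)
        out[f"{s}_p"] = p
        out[f"{s}_size"] = np.where(evaluated, best_size[s], 0)
        out[f"{s}_value"] = best_val[s]
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"{s}_neglog10"] = np.where(evaluated, np.log10(1.0 / p), np.nan)
    het_cols = [f"mean_het{j + 1}_p" for j in range(table.n_pops)]
    out["outcome"] = [
        classify_pattern(
            [row[c] for c in het_cols], row["s2_fst_p"], row["mean_fst_p"],
            alpha=config.alpha,
        )
        for _, row in out.iterrows()
    ]
    return out


def _empty_result(stats: list[str]) -> pd.DataFrame:
    cols = ["name", "chrom", "pos", "n_sizes"]
    for s in stats:
        cols += [f"{s}_p", f"{s}_size", f"{s}_value", f"{s}_neglog10"]
    cols.append("outcome")
    return pd.DataFrame({c: [] for c in cols})


def top_locus(records: pd.DataFrame, statistic: str) -> pd.Series:
    """The scan's most extreme locus for one statistic: maximum -log10
    percentile, ties (e.g. at the 1/(r+1) resolution floor) broken by the
    more extreme raw window statistic."""
    col = f"{statistic}_p"
    if col not in records.columns:
        raise KeyError(f"no column {col} in scan results")
    sub = records.dropna(subset=[col])
    if sub.empty:
        raise ValueError("no evaluated loci in scan results")
    pmin = sub[col].min()
    tied = sub[sub[col] == pmin]
    vcol = f"{statistic}_value"
    if statistic_tail(statistic) == "lower":
        return tied.loc[tied[vcol].idxmin()]
    return tied.loc[tied[vcol].idxmax()]


def write_scan_output(records: pd.DataFrame, path) -> None:
    """Write the scan table as TSV; percentiles keep 10 significant digits
    so a re-read reproduces them at printed precision."""
    records.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scan_output(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "name" not in df.columns or "outcome" not in df.columns:
        raise ParseError(f"{path} is not a scan results table")
    return df
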