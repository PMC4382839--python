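"""Allele-frequency tables: parsing, validation, conversion and writing.

The scan consumes a plain-text table with one row per SNP and, for a
two-population comparison, six whitespace-separated columns::

    name  chrom  pos  het_pop1  het_pop2  fst

For ``n_pops > 2`` populations the layout generalises to ``n_pops``
heterozygosity columns followed by a single multi-population F_ST column.
Positions are 1-based base-pair coordinates. A header line is optional and
detected by a non-numeric third field; ``#`` starts a comment.

Genotype-count tables (name, chrom, pos, then per-population
``n_AA n_Aa n_aa`` triples) can be converted with :func:`convert_genotypes`,
which computes expected heterozygosity 2p(1-p) and a Wright/Nei-style
F_ST = (H_T - H_S)/H_T from the per-population allele frequencies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HET_MAX = 0.5  # maximum of 2p(1-p) for a biallelic locus


class ParseError(ValueError):
    """Malformed input line; message carries the 1-based line number."""


class ValidationError(ValueError):
    """Values violate the locus invariants (het range, fst range, pos > 0)."""


def het_columns(n_pops: int) -> list[str]:
    return [f"het{j + 1}" for j in range(n_pops)]


@dataclass(frozen=True)
class LocusRecord:
    """One biallelic SNP: identifier, location, per-population expected
    heterozygosity and the multi-population F_ST."""

    name: str
    chrom: str
    pos: int
    het: tuple[float, ...]
    fst: float

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValidationError(f"locus {self.name}: pos must be positive, got {self.pos}")
        if len(self.het) < 2:
            raise ValidationError(f"locus {self.name}: need >= 2 populations")
        for h in self.het:
            if not (0.0 <= h <= HET_MAX + 1e-12):
                raise ValidationError(
                    f"locus {self.name}: heterozygosity {h} outside [0, {HET_MAX}]"
                )
        if not (0.0 <= self.fst <= 1.0):
            raise ValidationError(f"locus {self.name}: fst {self.fst} outside [0, 1]")


@dataclass
class LocusTable:
    """Ordered panel of loci, grouped by chromosome and sorted by position.

    ``df`` columns: ``name, chrom, pos, het1..het{n_pops}, fst``. Duplicate
    positions are kept (windows run over record order) but flagged with a
    warning.
    """

    df: pd.DataFrame
    n_pops: int = 2

    def __post_init__(self) -> None:
        cols = ["name", "chrom", "pos", *het_columns(self.n_pops), "fst"]
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise ValidationError(f"LocusTable missing columns: {missing}")
        self.df = self.df.loc[:, cols].copy()
        self.df["pos"] = self.df["pos"].astype(np.int64)
        self.df = self.df.sort_values(
            ["chrom", "pos", "name"], kind="mergesort"
        ).reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        if (df["pos"] <= 0).any():
            bad = df.loc[df["pos"] <= 0, "name"].tolist()
            raise ValidationError(f"non-positive positions at loci {bad[:5]}")
        hets = df[het_columns(self.n_pops)].to_numpy(float)
        if np.any((hets < -1e-12) | (hets > HET_MAX + 1e-9)):
            bad = df.loc[np.any((hets < 0) | (hets > HET_MAX + 1e-9), axis=1), "name"]
            raise ValidationError(
                f"heterozygosity outside [0, {HET_MAX}] at loci {bad.tolist()[:5]}"
            )
        fst = df["fst"].to_numpy(float)
        if np.any((fst < -1e-12) | (fst > 1 + 1e-12)):
            bad = df.loc[(fst < 0) | (fst > 1), "name"]
            raise ValidationError(f"fst outside [0, 1] at loci {bad.tolist()[:5]}")
        dup = df.duplicated(subset=["chrom", "pos"], keep=False)
        if dup.any():
            warnings.warn(
                f"{int(dup.sum())} records share a (chrom, pos); keeping all",
                stacklevel=2,
            )

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def het_cols(self) -> list[str]:
        return het_columns(self.n_pops)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chromosome(self, chrom: str) -> pd.DataFrame:
        sub = self.df[self.df["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not in table ({self.chromosomes()})")
        return sub

    def records(self) -> Iterator[LocusRecord]:
        hc = self.het_cols
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield LocusRecord(
                name=str(d["name"]),
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                het=tuple(float(d[c]) for c in hc),
                fst=float(d["fst"]),
            )

    @classmethod
    def from_records(cls, records: Iterable[LocusRecord]) -> "LocusTable":
        records = list(records)
        if not records:
            raise ValidationError("cannot build a LocusTable from zero records")
        n_pops = len(records[0].het)
        if any(len(r.het) != n_pops for r in records):
            raise ValidationError("all records must have the same number of populations")
        df = pd.DataFrame(
            {
                "name": [r.name for r in records],
                "chrom": [r.chrom for r in records],
                "pos": [r.pos for r in records],
                **{
                    c: [r.het[j] for r in records]
                    for j, c in enumerate(het_columns(n_pops))
                },
                "fst": [r.fst for r in records],
            }
        )
        return cls(df, n_pops=n_pops)


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-population genotype counts (n_AA, n_Aa, n_aa) at one biallelic
    locus — the converter's input unit."""

    name: str
    chrom: str
    pos: int
    counts: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValidationError(f"locus {self.name}: pos must be positive")
        if len(self.counts) < 2:
            raise ValidationError(f"locus {self.name}: need counts for >= 2 populations")
        for trio in self.counts:
            if len(trio) != 3 or any(c < 0 for c in trio):
                raise ValidationError(
                    f"locus {self.name}: counts must be non-negative (n_AA, n_Aa, n_aa)"
                )

    @property
    def totals(self) -> tuple[int, ...]:
        return tuple(sum(trio) for trio in self.counts)


def genotype_counts_frame(records: Iterable[GenotypeCounts]) -> pd.DataFrame:
    """Assemble GenotypeCounts records into the tabular converter input."""
    records = list(records)
    if not records:
        raise ValidationError("no genotype records")
    n_pops = len(records[0].counts)
    if any(len(r.counts) != n_pops for r in records):
        raise ValidationError("all records must cover the same populations")
    data = {
        "name": [r.name for r in records],
        "chrom": [r.chrom for r in records],
        "pos": [r.pos for r in records],
    }
    for j in range(n_pops):
        data[f"n_AA{j + 1}"] = [r.counts[j][0] for r in records]
        data[f"n_Aa{j + 1}"] = [r.counts[j][1] for r in records]
        data[f"n_aa{j + 1}"] = [r.counts[j][2] for r in records]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# per-locus statistics


def expected_heterozygosity(p):
    """Expected heterozygosity 2p(1-p) of a biallelic locus.

    Accepts a scalar or array of allele frequencies in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    out = 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def fst_from_frequencies(freqs: Sequence[float], sizes: Sequence[float] | None = None) -> float:
    """Wright/Nei-style F_ST = (H_T - H_S)/H_T from population allele frequencies.

    H_S is the (optionally size-weighted) mean of per-population 2p(1-p);
    H_T uses the (weighted) mean frequency. Negative estimates are clamped
    to 0; a monomorphic total pool (H_T = 0) returns 0.

    Parameters
    ----------
    freqs : per-population frequencies of the same allele (>= 2 populations)
    sizes : optional per-population sample sizes used as weights; by default
        populations are weighted equally.
    """
    p = np.asarray(freqs, dtype=float)
    if p.size < 2:
        raise ValueError("need allele frequencies from at least two populations")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    if sizes is not None:
        w = np.asarray(sizes, dtype=float)
        if w.shape != p.shape or np.any(w <= 0):
            raise ValueError("sizes must be positive, one per population")
        w = w / w.sum()
    else:
        w = np.full(p.shape, 1.0 / p.size)
    h_s = float(np.sum(w * 2.0 * p * (1.0 - p)))
    p_bar = float(np.sum(w * p))
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    if h_t == 0.0:
        return 0.0
    return float(np.clip((h_t - h_s) / h_t, 0.0, 1.0))


def _fst_matrix(freqs: np.ndarray) -> np.ndarray:
    """Vectorised unweighted (H_T - H_S)/H_T over a (loci x pops) matrix."""
    h_s = np.mean(2.0 * freqs * (1.0 - freqs), axis=1)
    p_bar = freqs.mean(axis=1)
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), 0.0)
    return np.clip(fst, 0.0, 1.0)


# ---------------------------------------------------------------------------
# six-column frequency format


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_frequency_table(path, n_pops: int = 2) -> LocusTable:
    """Read the whitespace-separated frequency table (six columns when
    ``n_pops = 2``): name, chrom, pos, one heterozygosity per population,
    then the multi-population F_ST.

    Rows are re-sorted by (chrom, pos). Malformed lines raise
    :class:`ParseError` naming the line; out-of-range values raise
    :class:`ValidationError` listing the offending loci.
    """
    if n_pops < 2:
        raise ValueError("n_pops must be >= 2")
    ncol = 3 + n_pops + 1
    names: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    hets: list[list[float]] = []
    fsts: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if not names and len(toks) >= 3 and not _is_number(toks[2]):
                continue  # header row
            if len(toks) != ncol:
                raise ParseError(
                    f"{path}:{lineno}: expected {ncol} columns for "
                    f"n_pops={n_pops}, found {len(toks)}"
                )
            try:
                pos = int(float(toks[2]))
                het = [float(t) for t in toks[3 : 3 + n_pops]]
                fst = float(toks[3 + n_pops])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            names.append(toks[0])
            chroms.append(toks[1])
            poss.append(pos)
            hets.append(het)
            fsts.append(fst)
    df = pd.DataFrame(
        {
            "name": names,
            "chrom": chroms,
            "pos": poss,
            **{c: [h[j] for h in hets] for j, c in enumerate(het_columns(n_pops))},
            "fst": fsts,
        }
    )
    return LocusTable(df, n_pops=n_pops)


def write_frequency_table(table: LocusTable, path) -> None:
    """Write a LocusTable as a tab-separated frequency file (with header).

    Round-trips through :func:`read_frequency_table` up to float formatting
    (six significant digits).
    """
    table.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# genotype-count conversion (the role of the original frequency converter)


def genotype_count_columns(n_pops: int) -> list[str]:
    cols = []
    for j in range(1, n_pops + 1):
        cols += [f"n_AA{j}", f"n_Aa{j}", f"n_aa{j}"]
    return cols


def read_genotype_table(path, n_pops: int = 2) -> pd.DataFrame:
    """Read a genotype-count table: name, chrom, pos, then per-population
    ``n_AA n_Aa n_aa`` triples (whitespace-separated, optional header)."""
    ncol = 3 + 3 * n_pops
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if not rows and len(toks) >= 3 and not _is_number(toks[2]):
                continue
            if len(toks) != ncol:
                raise ParseError(
                    f"{path}:{lineno}: expected {ncol} columns, found {len(toks)}"
                )
            try:
                rows.append(
                    [toks[0], toks[1], int(float(toks[2]))]
                    + [int(float(t)) for t in toks[3:]]
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric count ({exc})") from exc
    return pd.DataFrame(rows, columns=["name", "chrom", "pos"] + genotype_count_columns(n_pops))


def write_genotype_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def convert_genotypes(
    counts: pd.DataFrame,
    min_genotypes: int = 10,
    het_mode: str = "expected",
    weighted: bool = False,
) -> LocusTable:
    """Convert per-population genotype counts into the frequency table.

    Loci where ANY population has fewer than ``min_genotypes`` genotypes are
    dropped (the count filter; default 10). The allele frequency in each
    population is p = (2 n_AA + n_Aa) / 2N; heterozygosity is expected
    2p(1-p) by default, or the observed fraction n_Aa/N with
    ``het_mode="observed"``; F_ST is (H_T - H_S)/H_T (expected
    heterozygosities), size-weighted if ``weighted``.
    """
    if min_genotypes < 1:
        raise ValueError("min_genotypes must be >= 1")
    if het_mode not in ("expected", "observed"):
        raise ValueError("het_mode must be 'expected' or 'observed'")
    n_pops = (len(counts.columns) - 3) // 3
    cc = genotype_count_columns(n_pops)
    arr = counts[cc].to_numpy(float)
    if np.any(arr < 0):
        raise ValidationError("negative genotype counts")
    n_aa = arr[:, 0::3]
    n_ab = arr[:, 1::3]
    n_bb = arr[:, 2::3]
    totals = n_aa + n_ab + n_bb  # loci x pops
    keep = np.all(totals >= min_genotypes, axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "convert_genotypes: dropped %d/%d loci with < %d genotypes in some population",
            n_dropped, len(counts), min_genotypes,
        )
    kept = counts.loc[keep].reset_index(drop=True)
    if kept.empty:
        warnings.warn("convert_genotypes: no loci survive the genotype-count filter")
        df = pd.DataFrame(
            {"name": [], "chrom": [], "pos": [],
             **{c: [] for c in het_columns(n_pops)}, "fst": []}
        )
        return LocusTable(df, n_pops=n_pops)
    n_aa, n_ab, n_bb, totals = (a[keep] for a in (n_aa, n_ab, n_bb, totals))
    p = (2 * n_aa + n_ab) / (2 * totals)
    if het_mode == "expected":
        het = 2.0 * p * (1.0 - p)
    else:
        het = n_ab / totals
    if weighted:
        w = totals / totals.sum(axis=1, keepdims=True)
        h_s = np.sum(w * 2 * p * (1 - p), axis=1)
        p_bar = np.sum(w * p, axis=1)
        h_t = 2 * p_bar * (1 - p_bar)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), 0.0)
        fst = np.clip(fst, 0.0, 1.0)
    else:
        fst = _fst_matrix(p)
    df = pd.DataFrame(
        {
            "name": kept["name"].to_numpy(),
            "chrom": kept["chrom"].to_numpy(),
            "pos": kept["pos"].to_numpy(),
            **{c: het[:, j] for j, c in enumerate(het_columns(n_pops))},
            "fst": fst,
        }
    )
    return LocusTable(df, n_pops=n_pops)
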