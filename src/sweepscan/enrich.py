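"""Gene-level enrichment: do candidate genes collect extreme scan scores?

Each gene interval (BED, half-open 0-based) is assigned the maximum -log10
best percentile of a chosen statistic over the loci it contains (optionally
extended by a flank); a candidate gene list is then compared against random
same-size gene sets drawn from all scored genes, giving an empirical
permutation p-value. The max summary captures single-peak sweeps; note that
longer genes collect higher maxima, so matching random sets on gene length
or SNP count (``match_loci=True``) reduces that bias.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scan import statistic_tail

logger = logging.getLogger(__name__)

BED_COLS = ["chrom", "start", "end", "gene"]


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic extent: half-open 0-based [start, end) as in BED.
    A locus at 1-based position p lies inside iff start < p <= end."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"{self.gene}: need 0 <= start < end")


def read_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED (chrom, start, end, name; extra columns
    ignored). Coordinates stay half-open 0-based."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split()
            if len(toks) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs chrom start end name")
            chrom, start, end, gene = toks[0], int(toks[1]), int(toks[2]), toks[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            rows.append((chrom, start, end, gene))
    return pd.DataFrame(rows, columns=BED_COLS)


def score_genes(
    records: pd.DataFrame,
    genes: pd.DataFrame,
    statistic: str = "s2_fst",
    flank: int = 0,
    summary: str = "max",
) -> pd.DataFrame:
    """Assign each gene a scan score for one statistic.

    ``records`` is a scan results table; ``genes`` a BED-style frame
    (columns ``chrom start end gene``). The gene score is the max (or mean,
    with ``summary="mean"``) of ``{statistic}_neglog10`` over loci whose
    1-based position falls in (start - flank, end + flank]. Genes containing
    no locus are returned with ``scored=False`` and NaN score.
    """
    if summary not in ("max", "mean"):
        raise ValueError("summary must be 'max' or 'mean'")
    col = f"{statistic}_neglog10"
    if col not in records.columns:
        raise KeyError(f"scan results lack column {col}")
    out_rows = []
    rec_by_chrom = {c: g for c, g in records.groupby("chrom")}
    for g in genes.itertuples(index=False):
        sub = rec_by_chrom.get(g.chrom)
        if sub is None:
            loci = pd.Series(dtype=float)
        else:
            inside = (sub["pos"] > g.start - flank) & (sub["pos"] <= g.end + flank)
            loci = sub.loc[inside, col].dropna()
        if loci.empty:
            out_rows.append((g.gene, g.chrom, g.start, g.end, 0, np.nan, False))
        else:
            score = float(loci.max() if summary == "max" else loci.mean())
            out_rows.append((g.gene, g.chrom, g.start, g.end, len(loci), score, True))
    out = pd.DataFrame(
        out_rows, columns=["gene", "chrom", "start", "end", "n_loci", "score", "scored"]
    )
    if not out["scored"].any():
        raise ValueError("no gene interval overlaps any scanned locus")
    return out


@dataclass
class GeneSetResult:
    """Outcome of the random-gene-set comparison: the candidate summary, the
    null summaries, and the inclusive-rank empirical p floored at
    1/(n_random+1)."""

    candidate_score: float
    null_scores: np.ndarray
    p_value: float
    n_candidates: int
    excluded: tuple[str, ...]
    seed: int


def gene_set_test(
    scores: pd.DataFrame,
    candidates,
    n_random: int = 1000,
    seed: int = 0,
    summary: str = "mean",
    match_loci: bool = False,
) -> GeneSetResult:
    """Test whether candidate genes are enriched for extreme scan scores.

    The candidate summary (mean of candidate gene scores by default) is
    ranked against ``n_random`` random gene sets of the same size drawn
    uniformly WITHOUT replacement from all scored genes. With
    ``match_loci=True`` random genes are drawn from locus-count strata
    matching the candidates, countering the long-gene bias. Unscored
    candidates are dropped with a warning; empirical p is the inclusive
    fraction of null summaries >= the candidate summary, floored at
    1/(n_random+1).
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100 for a usable resolution")
    scored = scores[scores["scored"]].set_index("gene")
    candidates = list(dict.fromkeys(candidates))
    excluded = tuple(g for g in candidates if g not in scored.index)
    kept = [g for g in candidates if g in scored.index]
    if excluded:
        warnings.warn(f"{len(excluded)} candidate genes unscored; excluded: {excluded[:5]}")
    if not kept:
        raise ValueError("no candidate gene carries a score")
    # summaries run over sorted values so that equal score multisets give
    # bit-identical results regardless of draw order
    agg = (lambda v: float(np.mean(np.sort(v)))) if summary == "mean" else (
        lambda v: float(np.max(v)))
    cand_score = agg(scored.loc[kept, "score"].to_numpy())
    rng = np.random.default_rng(seed)
    pool_scores = scored["score"].to_numpy()
    k = len(kept)
    null = np.empty(n_random)
    if match_loci:
        strata = _locus_strata(scored["n_loci"].to_numpy())
        cand_strata = strata[[scored.index.get_loc(g) for g in kept]]
        by_stratum = {s: np.flatnonzero(strata == s) for s in np.unique(strata)}
        counts = {s: int((cand_strata == s).sum()) for s in np.unique(cand_strata)}
        for i in range(n_random):
            pick = np.concatenate(
                [rng.choice(by_stratum[s], size=c, replace=False) for s, c in counts.items()]
            )
            null[i] = agg(pool_scores[pick])
    else:
        for i in range(n_random):
            pick = rng.choice(len(pool_scores), size=k, replace=False)
            null[i] = agg(pool_scores[pick])
    p = max(float((null >= cand_score).mean()), 1.0 / (n_random + 1))
    return GeneSetResult(
        candidate_score=cand_score,
        null_scores=np.sort(null),
        p_value=p,
        n_candidates=k,
        excluded=excluded,
        seed=seed,
    )


def _locus_strata(n_loci: np.ndarray) -> np.ndarray:
    """Coarse strata of per-gene locus counts (quartile bins)."""
    qs = np.quantile(n_loci, [0.25, 0.5, 0.75])
    return np.searchsorted(qs, n_loci, side="right")
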