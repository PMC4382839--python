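"""Synthetic multi-population allele-frequency panels.

The neutral background is a Balding–Nichols-style frequency model: each
locus draws an ancestral frequency p (uniform on [0.05, 0.95] by default)
and every population's frequency from a Beta distribution with mean p and
variance F·p·(1−p), where F in (0, 1) controls differentiation (expected
F_ST grows with F). Loci are independent — a frequency-level stand-in for a
neutral genome, adequate because the scan consumes only per-locus
frequencies; coalescent simulators are the higher-fidelity alternative when
linkage structure matters.

Sweep signatures are injected post hoc on the summary columns:

* heterozygosity of the targeted population(s) is multiplied by a triangular
  ramp — ``het_reduction`` at the sweep center rising to 1 at the edges —
  emulating the diversity trough of a sweep;
* for post-split ("new") sweeps the per-locus F_ST inside the interval is
  re-drawn to alternate between near-1 and near-0 values, the mosaic left by
  fixation of alternative alleles on differing swept haplotypes, which is
  what drives the window F_ST variance up.

Genotype counts for converter tests come from Hardy–Weinberg multinomial
draws at the simulated frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_data import LocusTable, _fst_matrix, genotype_count_columns, het_columns


@dataclass
class NeutralModel:
    """Parameters of the neutral background.

    n_loci: loci per chromosome; n_chrom chromosomes named chr1, chr2, ...
    F: differentiation parameter in (0, 1) — the variance of population
       frequencies around the ancestral frequency is F·p·(1−p).
    ancestral_range: support of the uniform ancestral-frequency draw;
       bounded away from 0/1 so the panel is polymorphic, as on a SNP array.
    spacing: (min, max) base-pair gap between consecutive loci.
    """

    n_loci: int = 10_000
    n_pops: int = 2
    F: float = 0.1
    n_chrom: int = 1
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    spacing: tuple[int, int] = (500, 2000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.F < 1.0):
            raise ValueError(f"F must be in (0, 1), got {self.F}")
        if self.n_pops < 2:
            raise ValueError("need at least two populations")
        if self.n_loci < 1 or self.n_chrom < 1:
            raise ValueError("n_loci and n_chrom must be positive")


def simulate_frequencies(model: NeutralModel) -> pd.DataFrame:
    """Draw per-population allele frequencies under the neutral model.

    Returns a DataFrame with columns ``name, chrom, pos, p1..p{n_pops}``.
    Deterministic given ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    frames = []
    lo, hi = model.ancestral_range
    for c in range(1, model.n_chrom + 1):
        n = model.n_loci
        anc = rng.uniform(lo, hi, size=n)
        # Beta with mean p, variance F p (1-p): a = p(1-F)/F, b = (1-p)(1-F)/F
        a = anc * (1.0 - model.F) / model.F
        b = (1.0 - anc) * (1.0 - model.F) / model.F
        freqs = rng.beta(a[:, None], b[:, None], size=(n, model.n_pops))
        pos = np.cumsum(rng.integers(model.spacing[0], model.spacing[1] + 1, size=n))
        frames.append(
            pd.DataFrame(
                {
                    "name": [f"rs{c}_{i + 1}" for i in range(n)],
                    "chrom": f"chr{c}",
                    "pos": pos,
                    **{f"p{j + 1}": freqs[:, j] for j in range(model.n_pops)},
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frequencies_to_table(freqs: pd.DataFrame) -> LocusTable:
    """Summarise a frequency panel into the scan's input columns: expected
    heterozygosity 2p(1−p) per population and the unweighted multi-population
    F_ST = (H_T − H_S)/H_T."""
    pcols = [c for c in freqs.columns if c.startswith("p") and c[1:].isdigit()]
    n_pops = len(pcols)
    mat = freqs[pcols].to_numpy(float)
    df = freqs[["name", "chrom", "pos"]].copy()
    for j, c in enumerate(het_columns(n_pops)):
        df[c] = 2.0 * mat[:, j] * (1.0 - mat[:, j])
    df["fst"] = _fst_matrix(mat)
    return LocusTable(df, n_pops=n_pops)


def simulate_neutral(model: NeutralModel) -> LocusTable:
    """Neutral LocusTable: frequencies from the Balding–Nichols model,
    summarised by the same heterozygosity/F_ST formulas as the converter."""
    return frequencies_to_table(simulate_frequencies(model))


@dataclass(frozen=True)
class SweepSpec:
    """An injected sweep.

    center_index: locus index of the sweep center within its chromosome.
    half_width: loci affected on each side of the center.
    mode: 'old' (shared pre-split sweep: all populations' heterozygosity
       reduced, F_ST untouched), 'new_one_pop' (sweep in ``target_pop``
       only, oscillating F_ST), or 'new_both' (all populations swept,
       oscillating F_ST).
    het_reduction: multiplicative diversity factor at the center, in [0, 1);
       ramps linearly to 1 at the interval edges.
    fixation: re-draw F_ST inside the interval as the alternating
       high/low mosaic of alternative fixation (new modes only).
    """

    chrom: str = "chr1"
    center_index: int = 0
    half_width: int = 0
    mode: str = "new_one_pop"
    het_reduction: float = 0.1
    fixation: bool = True
    target_pop: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("old", "new_one_pop", "new_both"):
            raise ValueError(f"unknown sweep mode {self.mode!r}")
        if not (0.0 <= self.het_reduction < 1.0):
            raise ValueError("het_reduction must be in [0, 1)")
        if self.half_width < 0 or self.center_index < 0:
            raise ValueError("center_index and half_width must be non-negative")

    @property
    def interval(self) -> tuple[int, int]:
        """Affected locus-index interval, inclusive."""
        return (self.center_index - self.half_width, self.center_index + self.half_width)


FIX_HIGH = (0.85, 1.0)  # F_ST range for loci on alternatively fixed haplotype tracts
FIX_LOW = (0.0, 0.05)  # F_ST range for the interleaved undifferentiated loci


def inject_sweep(table: LocusTable, spec: SweepSpec, seed: int = 0) -> LocusTable:
    """Return a copy of ``table`` with one sweep signature injected.

    Only loci inside the affected interval change; everything else is
    bit-identical. See :class:`SweepSpec` for the signature anatomy.
    """
    lo, hi = spec.interval
    chrom_idx = np.flatnonzero((table.df["chrom"] == spec.chrom).to_numpy())
    if len(chrom_idx) == 0:
        raise ValueError(f"chromosome {spec.chrom!r} not in table")
    if lo < 0 or hi >= len(chrom_idx):
        raise ValueError(
            f"sweep interval [{lo}, {hi}] outside chromosome "
            f"{spec.chrom} with {len(chrom_idx)} loci"
        )
    df = table.df.copy()
    rows = chrom_idx[lo : hi + 1]
    offsets = np.arange(lo, hi + 1) - spec.center_index
    denom = max(spec.half_width, 1)
    ramp = spec.het_reduction + (1.0 - spec.het_reduction) * np.abs(offsets) / denom

    if spec.mode == "old" or spec.mode == "new_both":
        targets = list(range(table.n_pops))
    else:
        if not (0 <= spec.target_pop < table.n_pops):
            raise ValueError(f"target_pop {spec.target_pop} out of range")
        targets = [spec.target_pop]
    for j in targets:
        col = het_columns(table.n_pops)[j]
        df.iloc[rows, df.columns.get_loc(col)] = (
            df.iloc[rows, df.columns.get_loc(col)].to_numpy() * ramp
        )

    if spec.mode in ("new_one_pop", "new_both") and spec.fixation:
        rng = np.random.default_rng(seed)
        k = len(rows)
        high = rng.uniform(*FIX_HIGH, size=k)
        low = rng.uniform(*FIX_LOW, size=k)
        alternating = np.where(np.arange(lo, hi + 1) % 2 == 0, high, low)
        df.iloc[rows, df.columns.get_loc("fst")] = alternating
    return LocusTable(df, n_pops=table.n_pops)


def inject_sweeps(table: LocusTable, specs: Sequence[SweepSpec], seed: int = 0) -> LocusTable:
    """Inject several sweeps; intervals on the same chromosome must be
    disjoint (overlapping signatures would overwrite each other)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in specs:
        by_chrom.setdefault(s.chrom, []).append(s.interval)
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs)
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 <= a1:
                raise ValueError(f"overlapping sweep intervals on {chrom}: {ivs}")
    out = table
    for i, s in enumerate(specs):
        out = inject_sweep(out, s, seed=seed + i)
    return out


def sample_genotype_counts(
    freqs: pd.DataFrame, n: int | Sequence[int], seed: int = 0
) -> pd.DataFrame:
    """Hardy–Weinberg multinomial genotype counts at the given frequencies.

    ``freqs`` is a frequency panel (``simulate_frequencies`` layout);
    ``n`` is the number of genotyped individuals per population (scalar or
    one per population). Returns the genotype-count table layout consumed by
    :func:`sweepscan.allele_data.convert_genotypes`.
    """
    pcols = [c for c in freqs.columns if c.startswith("p") and c[1:].isdigit()]
    n_pops = len(pcols)
    sizes = np.broadcast_to(np.asarray(n, dtype=int), (n_pops,))
    if np.any(sizes < 1):
        raise ValueError("need at least one genotype per population")
    rng = np.random.default_rng(seed)
    out = freqs[["name", "chrom", "pos"]].copy()
    for j in range(n_pops):
        p = freqs[pcols[j]].to_numpy(float)
        probs = np.stack([p * p, 2 * p * (1 - p), (1 - p) ** 2], axis=1)
        counts = rng.multinomial(sizes[j], probs)
        out[f"n_AA{j + 1}"] = counts[:, 0]
        out[f"n_Aa{j + 1}"] = counts[:, 1]
        out[f"n_aa{j + 1}"] = counts[:, 2]
    return out[["name", "chrom", "pos"] + genotype_count_columns(n_pops)]
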