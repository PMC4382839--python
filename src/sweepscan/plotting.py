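"""Chromosome-wide tracks of -log10 percentiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .scan import statistic_ids

TRACK_COLORS = {"mean_fst": "#777777", "s2_fst": "#c0392b"}


def plot_scan(
    records: pd.DataFrame,
    chrom: str,
    path,
    statistics: list[str] | None = None,
) -> None:
    """Plot -log10 best-percentile tracks along one chromosome.

    One panel per statistic, position in Mb on the x axis. Raises if the
    chromosome has no scanned loci, listing the available ones.
    """
    sub = records[records["chrom"] == chrom]
    if sub.empty:
        avail = sorted(records["chrom"].unique().tolist())
        raise ValueError(f"no scan records for chromosome {chrom!r}; available: {avail}")
    if statistics is None:
        statistics = [
            s for s in _detect_statistics(records) if f"{s}_neglog10" in records.columns
        ]
    mb = sub["pos"].to_numpy(float) / 1e6
    fig, axes = plt.subplots(
        len(statistics), 1, figsize=(10, 1.9 * len(statistics)),
        sharex=True, squeeze=False,
    )
    for ax, stat in zip(axes[:, 0], statistics):
        ax.plot(mb, sub[f"{stat}_neglog10"], lw=0.7,
                color=TRACK_COLORS.get(stat, "#2c3e50"))
        ax.set_ylabel(f"-log10 p\n{stat}", fontsize=8)
        ax.tick_params(labelsize=8)
    axes[-1, 0].set_xlabel(f"{chrom} position (Mb)")
    fig.suptitle(f"Selection scan, {chrom}", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _detect_statistics(records: pd.DataFrame) -> list[str]:
    n_pops = sum(1 for c in records.columns if c.startswith("mean_het") and c.endswith("_p"))
    return statistic_ids(n_pops)
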