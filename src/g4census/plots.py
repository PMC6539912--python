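"""Convenience plots for cohort runs (optional; requires matplotlib/seaborn)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .cohort_stats import GenomeSummary, genome_summary_frame


def cohort_plots(summaries: Sequence[GenomeSummary], out_dir: str | Path, level: str = "group") -> list[Path]:
    """Write a per-group density boxplot and a GC-vs-density scatter.

    Returns the written paths.  Imported lazily so the pipeline has no hard
    plotting dependency.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    out_dir = Path(out_dir)
    df = genome_summary_frame(summaries)
    key = "group" if level == "group" else "subgroup"
    written = []

    fig, ax = plt.subplots(figsize=(6, 4))
    sns.boxplot(data=df, x=key, y="freq_per_kbp", ax=ax)
    ax.set_ylabel("PQS per 1000 bp")
    fig.tight_layout()
    p = out_dir / f"freq_boxplot_{level}.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    sns.scatterplot(data=df, x="gc_percent", y="freq_per_kbp", hue=key, ax=ax)
    ax.set_xlabel("GC %")
    ax.set_ylabel("PQS per 1000 bp")
    fig.tight_layout()
    p = out_dir / "gc_vs_freq.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)
    return written
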