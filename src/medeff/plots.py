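"""Optional figures: efficiency timeline and largest-slack bar chart."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless; figure files only
import matplotlib.pyplot as plt
import pandas as pd


def plot_timeline(timeline: pd.DataFrame, path: str | Path) -> Path:
    """Scatter of efficiency against approval year, one point per drug."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.scatter(timeline["approval_year"], timeline["efficiency"], s=28, alpha=0.8)
    ax.set_xlabel("FDA approval year")
    ax.set_ylabel("medication efficiency (1 − θ*)")
    ax.set_ylim(-0.02, 1.05)
    ax.grid(True, alpha=0.3)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_slack_bars(summary: dict[str, int], path: str | Path) -> Path:
    """Bar chart of how many drugs have their biggest slack in each variable."""
    fig, ax = plt.subplots(figsize=(6, 4))
    names = list(summary)
    ax.bar(names, [summary[n] for n in names])
    ax.set_ylabel("drugs with biggest slack")
    ax.tick_params(axis="x", rotation=20)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
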