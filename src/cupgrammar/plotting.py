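"""Bar-chart export of per-category strategy percentages by group."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .classifier import StrategyLabel
from .metrics import GroupSummary

__all__ = ["strategy_profile_chart"]


def strategy_profile_chart(
    groups: Sequence[GroupSummary], path, *, pooled: bool = False
):
    """One panel per group, bars for the nine category percentages.

    Uses the unweighted per-participant means by default (``pooled=True``
    switches to pooled-count percentages). Writes the figure to ``path``.
    """
    n = len(groups)
    fig, axes = plt.subplots(
        1, n, figsize=(2.2 * n + 1, 3.2), sharey=True, squeeze=False
    )
    labels = [lab.value for lab in StrategyLabel]
    for ax, g in zip(axes[0], groups):
        pct = g.pooled_pct if pooled else g.mean_pct
        ax.bar(range(len(labels)), [pct[lab] for lab in StrategyLabel])
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=90, fontsize=7)
        ax.set_title(f"{g.group_label}\n(n={g.n_trials})", fontsize=8)
    axes[0][0].set_ylabel("% of manipulative actions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
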