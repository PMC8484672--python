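"""Minimal plotting helper: violin plots of index distributions.

Optional; requires matplotlib (``pip install manatee-bci[plot]``).
"""

from __future__ import annotations

from .scoring import BCIScoreTable


def violin_by_group(scores: BCIScoreTable, model: str = "bci1",
                    group_by: str = "habitat", ax=None):
    """Violin plot of one index's scores split by a grouping column."""
    import matplotlib.pyplot as plt

    frame = scores.for_index(model)
    groups = sorted(frame[group_by].dropna().unique())
    data = [frame.loc[frame[group_by] == g, "score"].to_numpy() for g in groups]
    if ax is None:
        _, ax = plt.subplots()
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(groups) + 1), groups)
    ax.set_ylabel(model)
    ax.set_xlabel(group_by)
    return ax
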