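"""Plotting: sensitivity by group, domain, and orientation."""

from __future__ import annotations

import pandas as pd


def plot_sensitivity(cohort: pd.DataFrame, ax=None):
    """Point plot of mean sensitivity (+/- between-subject SEM) per
    condition, split by group — the standard way to display the 2x2x2
    threshold pattern.  Returns the matplotlib Axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    summary = (
        cohort.groupby(["group", "domain", "orientation"])["sensitivity"]
        .agg(["mean", "sem"])
        .reset_index()
    )
    offsets = {"expert": -0.06, "novice": 0.06}
    xticks = ["bird\nupright", "bird\ninverted", "human\nupright", "human\ninverted"]
    positions = {("bird", "upright"): 0, ("bird", "inverted"): 1,
                 ("human", "upright"): 2, ("human", "inverted"): 3}
    for group, g in summary.groupby("group"):
        x = [positions[(d, o)] + offsets.get(group, 0.0)
             for d, o in zip(g["domain"], g["orientation"])]
        ax.errorbar(x, g["mean"], yerr=g["sem"], fmt="o", capsize=3, label=group)
    ax.set_xticks(range(4), xticks)
    ax.set_ylabel("sensitivity (noise dots at ~79% correct)")
    ax.legend(title="group")
    return ax
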