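"""Bubble-chart rendering of stage-assignment tables (optional extra).

Thin matplotlib layer: the x axis is developmental time (absolute hours,
or relative time when event times are supplied), the y axis disc stage,
and each bubble's area is the proportion of simulated discs assigned to
that stage at that time point.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt

from .simclassify import AssignmentTable
from .timeline import EventTimes, relative_time


def bubble_plot(
    assignment: AssignmentTable,
    events: EventTimes | None = None,
    ax: "plt.Axes | None" = None,
    color: str = "C0",
    max_area: float = 600.0,
) -> "plt.Axes":
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    labels = list(assignment.frame.columns)
    ranks = {lab: i for i, lab in enumerate(labels)}
    xs, ys, sizes = [], [], []
    marks = []
    for (time_h, event), row in assignment.frame.iterrows():
        x = (
            relative_time(time_h, events, event=event)
            if events is not None
            else time_h
        )
        if event in ("moult", "wandering", "pupariation"):
            marks.append((x, {"moult": "m", "wandering": "w",
                              "pupariation": "wpp"}[event]))
        for lab, p in row.items():
            if p > 0:
                xs.append(x)
                ys.append(ranks[lab])
                sizes.append(p * max_area)
    ax.scatter(xs, ys, s=sizes, alpha=0.6, color=color,
               label=assignment.condition, edgecolors="none")
    for x, tag in marks:
        ax.annotate(tag, (x, len(labels) - 0.4), ha="center", fontsize=8)
    ax.set_yticks(range(len(labels)), labels)
    ax.set_ylabel("disc stage")
    ax.set_xlabel(
        "relative developmental time" if events is not None else "time (h AL3E)"
    )
    ax.set_title(f"Stage assignment: {assignment.condition}")
    return ax
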