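"""Optional figure renderers.

The pipeline itself emits long-format tables; these helpers turn them into
the two standard diagnostic figures: per-diet prediction boxplots with the
combined equation overlaid, and the equation-level random-intercept dot
plot.
"""

from __future__ import annotations

import numpy as np

from .combine import CombinedEquation, CombinedEquationResults
from .equations import PredictionSet


def plot_prediction_boxplots(
    preds: PredictionSet,
    equation: CombinedEquation | None = None,
    ax=None,
):
    """Boxplot of per-diet predictions across equations, ordered by NDF.

    Overlays the combined-equation prediction per diet when given.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4.5))
    frame = preds.frame
    order = (
        frame.groupby("diet_id", sort=False)["ndf_pct"]
        .first()
        .sort_values()
        .index.tolist()
    )
    data = [frame.loc[frame["diet_id"] == d, "ch4_g_per_kg_dm"] for d in order]
    ax.boxplot(data, tick_labels=order)
    if equation is not None:
        per_diet = frame.drop_duplicates("diet_id").set_index("diet_id")
        yhat = [
            equation.predict_frame(per_diet.loc[[d]].reset_index())[0] for d in order
        ]
        ax.plot(range(1, len(order) + 1), yhat, "o", color="tab:blue", zorder=3,
                label="combined equation")
        ax.legend()
    ax.set_xlabel("diet (ordered by NDF content)")
    ax.set_ylabel("CH$_4$ (g/kg DM)")
    return ax


def plot_random_effects(results: CombinedEquationResults, ax=None):
    """Dot plot of the equation-level random intercepts (BLUPs)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 7))
    items = sorted(results.random_effects.items(), key=lambda kv: kv[1])
    names = [k for k, _ in items]
    vals = np.array([v for _, v in items])
    colors = ["tab:red" if v < 0 else "tab:blue" for v in vals]
    ax.scatter(vals, range(len(vals)), c=colors, s=18)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(range(len(vals)), names, fontsize=7)
    ax.set_xlabel("random intercept (g CH$_4$/kg DM)")
    return ax
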