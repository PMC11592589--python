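"""Simple accuracy-vs-sigma line plots for sweep results."""

from __future__ import annotations

__all__ = ["plot_sweep"]


def plot_sweep(result, ax=None, by="noise_type", metric="accuracy", **kwargs):
    """One line per (condition, noise type) group: mean ``metric`` over
    replicates as a function of sigma.  Returns the matplotlib Axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = result.table
    group_cols = ["condition", "noise_type"]
    for (cond, nt), sub in t.groupby(group_cols, sort=True):
        mean = sub.groupby("sigma")[metric].mean()
        label = nt if t.condition.nunique() == 1 else f"{cond} / {nt}"
        ax.plot(mean.index, mean.values, marker="o", label=label, **kwargs)
    ax.set_xlabel("noise standard deviation (sigma, log-odds scale)")
    ax.set_ylabel(metric.replace("_", " "))
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    return ax
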