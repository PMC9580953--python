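"""Optional curve plotting (requires matplotlib, the ``plot`` extra)."""

from __future__ import annotations

from .curves import PanGenomeProfile


def plot_accumulation_curves(profile: PanGenomeProfile, path=None):
    """Plot aggregated pan and core curves with interquartile bands.

    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(6, 4))
    N = profile.N
    for stat, color, label in (
        ("pan", "tab:blue", "pan-genome"),
        ("core", "salmon", "core genome"),
    ):
        arr = getattr(profile, stat)
        ax.plot(N, profile.aggregate(stat), color=color, label=label)
        ax.fill_between(
            N,
            np.quantile(arr, 0.25, axis=0),
            np.quantile(arr, 0.75, axis=0),
            color=color,
            alpha=0.25,
            linewidth=0,
        )
    ax.set_xlabel("genome number N")
    ax.set_ylabel("gene families n")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
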