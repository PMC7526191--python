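"""Basic Manhattan-style plot of the per-window scan scores."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .freq import METHOD_TAILS, critical_z  # noqa: E402


def manhattan(window_table, path, p_threshold: float = 0.005) -> None:
    """One panel per method: window midpoint vs Z score, with the
    one-sided cut-off line at the given tail probability."""
    methods = [m for m in METHOD_TAILS if f"z_{m}" in window_table.columns]
    fig, axes = plt.subplots(
        len(methods), 1, figsize=(10, 2.2 * len(methods)), sharex=True, squeeze=False
    )
    mid = (window_table["start"] + window_table["end"]) / 2
    for ax, m in zip(axes.ravel(), methods):
        ax.scatter(mid, window_table[f"z_{m}"], s=4, c="steelblue")
        cut = critical_z(p_threshold, tail=METHOD_TAILS[m])
        ax.axhline(cut, color="black", lw=0.8, ls="--")
        ax.set_ylabel(f"Z {m}")
    axes.ravel()[-1].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
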