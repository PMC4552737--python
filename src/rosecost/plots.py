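"""Optional static figures (matplotlib): tornado diagram and PSA histogram.

Plotting is a convenience on top of the emitted data tables, not part of
the analysis surface; matplotlib is imported lazily so the rest of the
package has no hard dependency on it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence


def tornado(one_way_results: Sequence, base_delta: float, path: str | Path, title: str = "") -> Path:
    """Draw a tornado diagram from :func:`rosecost.sensitivity.one_way` output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = list(one_way_results)[::-1]  # widest bar on top
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(results) + 1.5))
    for i, r in enumerate(results):
        lo, hi = sorted((r.delta_at_low, r.delta_at_high))
        ax.barh(i, hi - lo, left=lo, color="#4878a8", height=0.6)
    ax.axvline(base_delta, color="k", lw=1, ls="--", label="base ΔTC")
    ax.set_yticks(range(len(results)), [r.parameter for r in results])
    ax.set_xlabel("ΔTC per case (ROSE − fixed), $")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def psa_histogram(deltas, path: str | Path, title: str = "") -> Path:
    """Histogram of per-draw ΔTC values from a probabilistic analysis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(deltas, bins=80, color="#4878a8")
    ax.axvline(0.0, color="k", lw=1, ls="--")
    ax.set_xlabel("ΔTC per case (ROSE − fixed), $")
    ax.set_ylabel("draws")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
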