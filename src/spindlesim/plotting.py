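"""Small plotting helpers (matplotlib optional, not a core dependency)."""

from __future__ import annotations

import numpy as np

from .observables import ProbabilityCurve


def plot_probability_curves(curves: dict[str, ProbabilityCurve], ax=None):
    """Step plot of event-probability curves, one line per label."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for label, c in curves.items():
        t = np.concatenate([[0.0], c.times])
        p = np.concatenate([[0.0], c.probability])
        ax.step(t, p, where="post", label=label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cumulative probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax


def plot_mt_count(times, counts, fit=None, ax=None):
    """Ensemble-mean MT count with an optional birth--death fit overlay."""
    import matplotlib.pyplot as plt
    from .mt_dynamics import expected_mt_count
    if ax is None:
        _, ax = plt.subplots()
    mean = np.asarray(counts).mean(axis=0) if np.ndim(counts) == 2 else counts
    ax.plot(times, mean, lw=1, label="ensemble mean")
    if fit is not None:
        ax.plot(times, expected_mt_count(fit.k_nucl_hat, fit.k_out_hat, times),
                "--", label=f"fit: k_out = {fit.k_out_hat:.3f}/s")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("MT count")
    ax.legend()
    return ax
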