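"""Basic figures: Wood's plot, E-histograms with fits, and the BVA arc.

Matplotlib-based convenience wrappers; each returns the axes it drew on so
callers can compose or save figures.
"""

from __future__ import annotations

import numpy as np

CLASS_COLOURS = {"protected": "tab:blue", "deprotected": "tab:red", "not significant": "0.6"}


def woods_plot(result, ax=None):
    """Summed uptake difference per peptide along the sequence, with the
    confidence threshold as dotted lines and class colouring."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for _, row in result.iterrows():
        ax.hlines(
            row["dd_sum"], row["start"], row["end"],
            color=CLASS_COLOURS.get(row["class"], "k"), lw=2.5,
        )
    th = result["threshold"].iloc[0]
    ax.axhline(th, ls=":", color="k", lw=0.8)
    ax.axhline(-th, ls=":", color="k", lw=0.8)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("residue")
    ax.set_ylabel("summed ΔD (Da)")
    return ax


def efret_histogram(distribution, ax=None, bins=50, color="tab:green"):
    """Burst/sample E histogram with the fitted Gaussian components."""
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.hist(distribution.samples, bins=bins, range=(0, 1), density=True,
            color=color, alpha=0.5)
    x = np.linspace(0, 1, 400)
    total = np.zeros_like(x)
    for mean, sd, weight in distribution.components:
        comp = weight * norm.pdf(x, mean, sd)
        total += comp
        ax.plot(x, comp, "--", color="0.3", lw=1)
    ax.plot(x, total, color="k", lw=1.5)
    ax.set_xlabel("E")
    ax.set_ylabel("density")
    return ax


def bva_plot(result, ax=None):
    """Per-burst sd vs E with the shot-noise arc and bin means."""
    import matplotlib.pyplot as plt

    from .bursts import shot_noise_sd

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(result.per_burst["e_prox"], result.per_burst["sd"], ".", ms=2,
            color="tab:blue", alpha=0.3)
    e = np.linspace(0, 1, 200)
    ax.plot(e, shot_noise_sd(e, result.window), "k-", lw=1.5, label="shot noise")
    good = result.bins[result.bins["n"] >= 20]
    ax.plot(good["e_mean"], good["sd_mean"], "o", mfc="w", mec="k", label="bin mean")
    ax.set_xlabel("E")
    ax.set_ylabel(f"sd of window E (n={result.window})")
    ax.legend(frameon=False)
    return ax
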