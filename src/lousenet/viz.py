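"""Minimal plotting plumbing: coefficient plots and null-distribution
histograms.  These are diagnostic outputs, not figure-quality graphics."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .models import ModelFit
from .permutation import PermutationResult


def coefficient_plot(fit: ModelFit, path) -> None:
    """Dot-and-line plot of fixed-effect estimates with +/- 1 SE."""
    names = fit.names[1:]                 # intercept omitted
    est = fit.params[1:]
    se = fit.bse[1:]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(names) + 1))
    y = np.arange(len(names))[::-1]
    ax.hlines(y, est - se, est + se, color="black")
    ax.plot(est, y, "o", color="black")
    ax.axvline(0, color="grey", lw=0.8, ls=":")
    ax.set_yticks(y)
    ax.set_yticklabels(names)
    ax.set_xlabel("estimate (z scale)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def null_distribution_plot(result: PermutationResult, path) -> None:
    """Histogram of beta_rand with the observed coefficient marked."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(result.beta_rand, bins=30, color="lightgrey", edgecolor="grey")
    ax.axvline(result.beta_obs, color="black", lw=1.5)
    ax.set_xlabel(f"beta_rand ({result.measure}, {result.term})")
    ax.set_title(f"p = {result.p_empirical:.3f} ({result.tail} tail, "
                 f"R = {result.config.R})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
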