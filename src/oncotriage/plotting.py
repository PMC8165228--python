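"""Optional plots mirroring the landscape panels and the oncoplot.

All functions return a matplotlib Figure and never call ``show``; use the
Agg backend in headless contexts.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; set before pyplot import
import matplotlib.pyplot as plt
import numpy as np

from .drivers import OncoplotMatrix
from .landscape import SPECTRUM_CLASSES, MutationTypeDistribution, SnvSpectrum, TmbResult


def plot_tmb(tmb: TmbResult):
    fig, ax = plt.subplots(figsize=(6, 3))
    samples = list(tmb.per_sample)
    ax.bar(samples, [tmb.per_sample[s] for s in samples], color="#4C72B0")
    if tmb.median is not None:
        ax.axhline(tmb.median, ls="--", c="grey", lw=1, label="median (cell lines)")
        ax.legend(frameon=False)
    ax.set_ylabel("mutations / Mb")
    ax.set_title("Tumor mutational burden")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    return fig


def plot_mutation_types(dist: MutationTypeDistribution):
    fig, ax = plt.subplots(figsize=(6, 3))
    props = dist.mean_proportions or dist.pooled_proportions or {}
    labels = [c.value for c in props]
    ax.bar(labels, list(props.values()), color="#55A868")
    ax.set_ylabel("proportion")
    ax.set_title("Distribution of mutation types")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    return fig


def plot_spectrum(spectrum: SnvSpectrum):
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(SPECTRUM_CLASSES, [spectrum.counts[c] for c in SPECTRUM_CLASSES],
           color=["#1f77b4", "#000000", "#d62728", "#7f7f7f", "#2ca02c", "#e377c2"])
    ax.set_ylabel("SNV count")
    ax.set_title("SNV spectrum (pyrimidine-collapsed)")
    fig.tight_layout()
    return fig


def plot_oncoplot(matrix: OncoplotMatrix):
    fig, ax = plt.subplots(
        figsize=(max(4, 0.6 * len(matrix.samples)), max(3, 0.35 * len(matrix.genes))))
    grid = np.array([
        [1.0 if matrix.cell(g, s) else 0.0 for s in matrix.samples]
        for g in matrix.genes
    ])
    ax.imshow(grid, cmap="Blues", aspect="auto", vmin=0, vmax=1)
    ax.set_xticks(range(len(matrix.samples)), matrix.samples, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.genes)), matrix.genes, fontsize=7)
    ax.set_title("Oncoplot (mutation presence)")
    fig.tight_layout()
    return fig
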