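"""Minimal figures: sorted eigengene bars with tumor/normal colors, age scatter."""

from __future__ import annotations

import numpy as np

from .eigengene import Eigengene, sort_samples_by_eigengene
from .io import SampleSheet

_GROUP_COLOR = {"tumor": "#c0392b", "normal": "#27ae60"}


def sorted_eigengene_bar(eg: Eigengene, sheet: SampleSheet, ax=None):
    """Bar plot of eigengene scores sorted high to low, tumor red / normal green."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(8, 2.5))
    order = sort_samples_by_eigengene(eg, sheet)
    scores = dict(zip(eg.sample_ids, eg.values))
    xs = np.arange(len(order))
    ax.bar(
        xs,
        [scores[s] for s, _g in order],
        color=[_GROUP_COLOR[g] for _s, g in order],
        width=1.0,
    )
    ax.set_xlabel("samples (sorted)")
    ax.set_ylabel("eigengene")
    ax.set_title(f"{eg.dataset} {eg.cluster_id}")
    return ax


def age_scatter(eg: Eigengene, sheet: SampleSheet, ax=None):
    """Eigengene score vs patient age."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(4, 3))
    aligned = sheet.aligned_to(eg.sample_ids)
    mask = ~np.isnan(aligned.ages)
    ax.scatter(eg.values[mask], aligned.ages[mask], s=8, alpha=0.6)
    ax.set_xlabel("eigengene")
    ax.set_ylabel("age (years)")
    ax.set_title(f"{eg.dataset} {eg.cluster_id}")
    return ax
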