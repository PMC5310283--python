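"""Probe filtering and gene mapping applied before network construction.

The filtering sequence for each dataset is:

1. drop probes with any missing value;
2. drop probes whose variance is strictly below the 30th percentile of the
   per-probe variances of the dataset;
3. drop probes whose mean is strictly below the 20th percentile of the
   per-probe means, the percentile being computed over the probes that
   survived the variance stage (the filters are applied sequentially).

Percentiles use linear interpolation between order statistics (the numpy
default).  Datasets with fewer than 50 samples are meant to be skipped by
the pipeline driver (:func:`check_min_samples`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError
from .io import BetaMatrix, ProbeAnnotation

logger = logging.getLogger("panmethyl")


@dataclass(frozen=True)
class FilterReport:
    """Per-stage removal counts from :func:`filter_probes`."""

    n_input: int
    n_removed_missing: int
    n_removed_variance: int
    n_removed_mean: int

    @property
    def n_output(self) -> int:
        return (
            self.n_input
            - self.n_removed_missing
            - self.n_removed_variance
            - self.n_removed_mean
        )


def filter_probes(
    bm: BetaMatrix,
    var_percentile: float = 30.0,
    mean_percentile: float = 20.0,
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the missing-value, low-variance and low-mean probe filters.

    Returns the filtered matrix (a copy) together with a
    :class:`FilterReport`.  Raises :class:`DataError` if no probe survives.
    """
    if bm.n_probes == 0:
        raise DataError("filter_probes: empty beta matrix")

    complete = ~np.isnan(bm.values).any(axis=1)
    n_missing = int((~complete).sum())
    stage1 = bm.select_probes(complete)
    if stage1.n_probes == 0:
        raise DataError("filter_probes: all probes removed (every probe has missing values)")

    variances = stage1.values.var(axis=1, ddof=1)
    var_thr = np.percentile(variances, var_percentile)
    keep_var = variances >= var_thr
    n_var = int((~keep_var).sum())
    stage2 = stage1.select_probes(keep_var)
    if stage2.n_probes == 0:
        raise DataError("filter_probes: all probes removed by the variance filter")

    means = stage2.values.mean(axis=1)
    mean_thr = np.percentile(means, mean_percentile)
    keep_mean = means >= mean_thr
    n_mean = int((~keep_mean).sum())
    out = stage2.select_probes(keep_mean)
    if out.n_probes == 0:
        raise DataError("filter_probes: all probes removed by the mean filter")

    report = FilterReport(bm.n_probes, n_missing, n_var, n_mean)
    logger.info(
        "filter_probes: %d -> %d probes (missing %d, low-variance %d, low-mean %d)",
        report.n_input, report.n_output, n_missing, n_var, n_mean,
    )
    return out, report


def restrict_to_common_probes(bm: BetaMatrix, reference_probe_ids) -> BetaMatrix:
    """Keep exactly the probes present in ``reference_probe_ids``, in ``bm`` order.

    Used to restrict 450K-platform data to the probes shared with the 27K
    platform so clusters from the two platforms are comparable.
    """
    ref = set(reference_probe_ids)
    if not ref:
        raise DataError("restrict_to_common_probes: empty reference probe list")
    keep = [p for p in bm.probe_ids if p in ref]
    if not keep:
        raise DataError("restrict_to_common_probes: no probes in common with the reference")
    return bm.select_probes(keep)


def check_min_samples(bm: BetaMatrix, min_n: int = 50) -> bool:
    """True iff the dataset has at least ``min_n`` samples (default 50)."""
    return bm.n_samples >= min_n


def map_probes_to_genes(probe_ids, ann: ProbeAnnotation) -> list[str]:
    """Coerce probes to an ordered, de-duplicated gene list.

    For a probe annotated with a multi-gene family only the first listed
    member is taken (avoids enrichment bias from gene families).  Probes
    without annotation are dropped with a warning.
    """
    out: list[str] = []
    seen: set[str] = set()
    n_unann = 0
    for p in probe_ids:
        genes = ann.genes_for(p)
        if not genes:
            n_unann += 1
            continue
        first = genes[0]
        if first not in seen:
            seen.add(first)
            out.append(first)
    if n_unann:
        logger.warning("map_probes_to_genes: %d probes without annotation dropped", n_unann)
    return out
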