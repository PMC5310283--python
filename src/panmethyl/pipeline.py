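"""Two-step study orchestration.

Step 1 mines co-methylation clusters per dataset (filter -> |SCC| network
-> weight balancing -> unit-max rescale -> lmQCM -> merge).  Step 2 pools
all per-dataset cluster edges, tallies cross-dataset frequencies and mines
the fraction-weighted network at gamma = 0.5 to obtain the frequent
(pan-cancer) clusters.  The downstream stage maps each frequent cluster
back into every dataset: SVD eigengene, tumor/normal separation AUC, age
correlation, plus cross-dataset Jaccard and edge-contribution reports.

Everything is deterministic given the inputs; the only randomness in a
synthetic study comes from the generator seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare as cmp
from .eigengene import age_correlation, compute_eigengene, separation_statistic
from .exceptions import DataError, PanmethylError
from .frequency import (
    EdgeFrequencyTable,
    build_frequency_network,
    clusters_to_edges,
    mine_frequent_clusters,
    tally_edge_frequencies,
    write_frequency_table,
)
from .io import (
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
)
from .lmqcm import Cluster, MinerParams, MiningTrace, merge_clusters, mine_clusters, write_clusters
from .network import build_scc_network, normalize_weights, rescale_unit_max
from .preprocess import check_min_samples, filter_probes, map_probes_to_genes, restrict_to_common_probes

logger = logging.getLogger("panmethyl")


# ---------------------------------------------------------------------------
# results containers


@dataclass
class Step1Result:
    labels: list[str]
    filtered: dict[str, BetaMatrix]
    clusters: dict[str, list[Cluster]]
    skipped: dict[str, str]
    manifest: dict


@dataclass
class Step2Result:
    table: EdgeFrequencyTable
    clusters: list[Cluster]
    trace: MiningTrace
    manifest: dict


@dataclass
class DownstreamResult:
    eigengenes: dict[tuple[str, str], object]
    summary: pd.DataFrame
    jaccard: pd.DataFrame | None
    contribution: pd.DataFrame
    crosscheck: dict[str, object] = field(default_factory=dict)


@dataclass
class StudyResult:
    step1: Step1Result
    step2: Step2Result
    downstream: DownstreamResult


# ---------------------------------------------------------------------------
# step 1


def mine_dataset(
    bm: BetaMatrix,
    params: MinerParams,
    label: str = "",
    trace: MiningTrace | None = None,
) -> list[Cluster]:
    """Network construction + lmQCM + merge for one filtered dataset."""
    net = build_scc_network(bm)
    net = normalize_weights(net)
    net = rescale_unit_max(net)
    mined = mine_clusters(net, params, source=label, trace=trace)
    merged = merge_clusters(mined, params.beta, net=net)
    return [c for c in merged if c.size >= params.min_size]


def run_step1(
    datasets: list[tuple[str, BetaMatrix, SampleSheet]],
    params: MinerParams | None = None,
    var_percentile: float = 30.0,
    mean_percentile: float = 20.0,
    min_samples: int = 50,
    reference_probes=None,
) -> Step1Result:
    """Filter and mine every dataset; skip (with a logged reason) datasets
    that fail the minimum-sample rule or error out.  Raises only if every
    dataset fails."""
    params = params or MinerParams()
    labels, filtered, clusters, skipped = [], {}, {}, {}
    manifest: dict = {"params": vars(params).copy(), "datasets": {}}
    for label, bm, _sheet in datasets:
        t0 = time.perf_counter()
        try:
            if not check_min_samples(bm, min_samples):
                reason = f"fewer than {min_samples} samples ({bm.n_samples})"
                logger.warning("step1[%s]: skipped, %s", label, reason)
                skipped[label] = reason
                manifest["datasets"][label] = {"skipped": reason}
                continue
            if reference_probes is not None:
                bm = restrict_to_common_probes(bm, reference_probes)
            fbm, report = filter_probes(bm, var_percentile, mean_percentile)
            cl = mine_dataset(fbm, params, label=label)
            labels.append(label)
            filtered[label] = fbm
            clusters[label] = cl
            manifest["datasets"][label] = {
                "n_samples": bm.n_samples,
                "n_probes_in": report.n_input,
                "removed_missing": report.n_removed_missing,
                "removed_variance": report.n_removed_variance,
                "removed_mean": report.n_removed_mean,
                "n_probes_used": report.n_output,
                "n_clusters": len(cl),
                "cluster_sizes": [c.size for c in cl],
                "seconds": round(time.perf_counter() - t0, 3),
            }
            logger.info(
                "step1[%s]: %d probes -> %d clusters (%.1fs)",
                label, report.n_output, len(cl), time.perf_counter() - t0,
            )
        except PanmethylError as e:
            logger.warning("step1[%s]: skipped after error: %s", label, e)
            skipped[label] = str(e)
            manifest["datasets"][label] = {"skipped": str(e)}
    if not labels:
        raise DataError("run_step1: every dataset failed or was skipped")
    return Step1Result(labels, filtered, clusters, skipped, manifest)


# ---------------------------------------------------------------------------
# step 2


def run_step2(
    step1: Step1Result,
    params: MinerParams | None = None,
) -> Step2Result:
    """Pool cluster edges across datasets, tally frequencies, mine the
    fraction-weighted network (gamma defaults to 0.5, no balancing)."""
    if len(step1.labels) < 2:
        raise DataError("run_step2: need step-1 output from at least 2 datasets")
    params = params or MinerParams(gamma=0.5)
    edge_sets = [clusters_to_edges(step1.clusters[lab]) for lab in step1.labels]
    table = tally_edge_frequencies(edge_sets)
    trace = MiningTrace()
    if table.entries:
        net = build_frequency_network(table)
        clusters = mine_frequent_clusters(net, params, trace=trace)
    else:
        clusters = []
    manifest = {
        "params": vars(params).copy(),
        "n_datasets_pooled": table.n_datasets,
        "n_distinct_pairs": len(table.entries),
        "frequency_histogram": table.histogram(),
        "n_frequent_clusters": len(clusters),
        "frequent_cluster_sizes": [c.size for c in clusters],
    }
    return Step2Result(table, clusters, trace, manifest)


# ---------------------------------------------------------------------------
# downstream


def run_downstream(
    step1: Step1Result,
    step2: Step2Result,
    sheets: dict[str, SampleSheet],
    annotation: ProbeAnnotation | None = None,
    reference_sets: dict[str, cmp.GeneSet] | None = None,
) -> DownstreamResult:
    """Eigengene + separation + age statistics per dataset x frequent
    cluster, plus Jaccard, edge-contribution and gene-list crosscheck
    reports."""
    eigengenes = {}
    rows = []
    for label in step1.labels:
        bm = step1.filtered[label]
        sheet = sheets[label]
        for k, cluster in enumerate(step2.clusters, start=1):
            cid = f"F{k}"
            try:
                eg = compute_eigengene(bm, cluster.probe_ids, cluster_id=cid, dataset=label)
            except PanmethylError as e:
                logger.info("downstream[%s/%s]: skipped (%s)", label, cid, e)
                continue
            eigengenes[(label, cid)] = eg
            sep = separation_statistic(eg, sheet)
            age = age_correlation(eg, sheet)
            rows.append(
                {
                    "dataset": label,
                    "cluster_id": cid,
                    "n_probes_used": len(eg.probe_ids),
                    "variance_explained": eg.variance_explained,
                    "auc": sep.auc if sep else np.nan,
                    "direction": sep.direction if sep else "",
                    "p_value": sep.p_value if sep else np.nan,
                    "age_scc": age.scc if age else np.nan,
                    "age_p": age.p_value if age else np.nan,
                    "age_n": age.n_used if age else 0,
                }
            )
    summary = pd.DataFrame(rows)

    jaccard = None
    if annotation is not None:
        gene_sets = [
            cmp.GeneSet(
                lab,
                tuple(
                    g
                    for c in step1.clusters[lab]
                    for g in map_probes_to_genes(c.probe_ids, annotation)
                ),
            )
            for lab in step1.labels
        ]
        jaccard = cmp.jaccard_matrix(gene_sets)

    contrib = pd.DataFrame(
        {
            lab: [
                cmp.edge_contribution(c, clusters_to_edges(step1.clusters[lab]))
                for c in step2.clusters
            ]
            for lab in step1.labels
        },
        index=[f"F{k}" for k in range(1, len(step2.clusters) + 1)],
    )

    crosscheck = {}
    if reference_sets and annotation is not None:
        pan_genes = {
            f"F{k}": cmp.GeneSet(
                f"F{k}", tuple(map_probes_to_genes(c.probe_ids, annotation))
            )
            for k, c in enumerate(step2.clusters, start=1)
        }
        for ref_name, ref in reference_sets.items():
            crosscheck[ref_name] = {
                cid: cmp.crosscheck_gene_lists(gs, ref) for cid, gs in pan_genes.items()
            }
    return DownstreamResult(eigengenes, summary, jaccard, contrib, crosscheck)


def run_study(
    datasets: list[tuple[str, BetaMatrix, SampleSheet]],
    annotation: ProbeAnnotation | None = None,
    step1_params: MinerParams | None = None,
    step2_params: MinerParams | None = None,
    var_percentile: float = 30.0,
    mean_percentile: float = 20.0,
    min_samples: int = 50,
    reference_sets=None,
) -> StudyResult:
    """Full step-1 + step-2 + downstream run over in-memory datasets."""
    step1 = run_step1(
        datasets,
        params=step1_params,
        var_percentile=var_percentile,
        mean_percentile=mean_percentile,
        min_samples=min_samples,
    )
    step2 = run_step2(step1, params=step2_params)
    sheets = {lab: sheet for lab, _bm, sheet in datasets}
    downstream = run_downstream(step1, step2, sheets, annotation, reference_sets)
    return StudyResult(step1, step2, downstream)


# ---------------------------------------------------------------------------
# file-based driver (CLI `run`)


@dataclass(frozen=True)
class DatasetEntry:
    label: str
    beta_path: str
    samples_path: str
    platform: str = ""


@dataclass(frozen=True)
class RunConfig:
    datasets: tuple[DatasetEntry, ...]
    out_dir: str
    annotation_path: str | None = None
    match_probes_path: str | None = None
    var_percentile: float = 30.0
    mean_percentile: float = 20.0
    min_samples: int = 50
    step1_gamma: float = 0.6
    step2_gamma: float = 0.5
    lam: float = 1.0
    t: float = 1.0
    beta: float = 0.4
    min_size: int = 20
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        obj = json.loads(Path(path).read_text())
        datasets = tuple(DatasetEntry(**d) for d in obj.pop("datasets"))
        return cls(datasets=datasets, **obj)


def run_from_config(config: RunConfig) -> StudyResult:
    """Load the datasets named in the config, run the full study and write
    all stage outputs under ``config.out_dir``."""
    if not config.datasets:
        raise DataError("run_from_config: no datasets configured")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    loaded = []
    for entry in config.datasets:
        bm = read_beta_matrix(entry.beta_path)
        sheet = read_sample_sheet(entry.samples_path).aligned_to(bm.sample_ids)
        loaded.append((entry.label, bm, sheet))
    annotation = (
        read_probe_annotation(config.annotation_path) if config.annotation_path else None
    )
    reference_probes = None
    if config.match_probes_path:
        reference_probes = [
            line.strip()
            for line in Path(config.match_probes_path).read_text().splitlines()
            if line.strip()
        ]
    p1 = MinerParams(config.step1_gamma, config.lam, config.t, config.beta, config.min_size)
    p2 = MinerParams(config.step2_gamma, config.lam, config.t, config.beta, config.min_size)
    step1 = run_step1(
        loaded,
        params=p1,
        var_percentile=config.var_percentile,
        mean_percentile=config.mean_percentile,
        min_samples=config.min_samples,
        reference_probes=reference_probes,
    )
    step2 = run_step2(step1, params=p2)
    sheets = {lab: sheet for lab, _bm, sheet in loaded}
    downstream = run_downstream(step1, step2, sheets, annotation)

    for lab in step1.labels:
        write_clusters(step1.clusters[lab], out / f"{lab}_clusters.tsv")
    write_frequency_table(step2.table, out / "edge_frequencies.tsv")
    write_clusters(step2.clusters, out / "frequent_clusters.tsv")
    if not downstream.summary.empty:
        downstream.summary.to_csv(out / "eigengene_summary.tsv", sep="\t", index=False)
    if downstream.jaccard is not None:
        downstream.jaccard.to_csv(out / "jaccard_matrix.tsv", sep="\t")
    downstream.contribution.to_csv(out / "edge_contribution.tsv", sep="\t")
    manifest = {
        "config": {
            **{k: v for k, v in vars(config).items() if k != "datasets"},
            "datasets": [vars(d) for d in config.datasets],
        },
        "step1": step1.manifest,
        "step2": step2.manifest,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return StudyResult(step1, step2, downstream)
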