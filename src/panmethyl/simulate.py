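"""Synthetic multi-dataset methylome studies with planted co-methylation modules.

Each study mimics a panel of tumor methylome cohorts (e.g. several cancer
types profiled on the same array): every dataset shares one probe
namespace, some latent co-methylated modules are planted in several
datasets, some in a single dataset, and the rest of the probes are
independent background.

Module probes follow a latent single-factor model pushed through the
inverse logit so beta values stay in (0, 1) and rank correlations are
invariant to the link:

    beta_ij = invlogit(baseline_mu + tumor_shift * 1[tumor_j]
                       + loading_i * f_j + eps_ij)

with ``f_j`` standard normal per sample (or bimodal for the
X-inactivation-like control module), ``eps_ij ~ N(0, noise_sd)``.
Background probes are inverse-logit of independent normals whose means
span low to high methylation.  Generation is a pure function of the seed;
per-dataset substreams are spawned deterministically from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .exceptions import ConfigurationError, DataError
from .io import (
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    write_beta_matrix,
    write_probe_annotation,
    write_sample_sheet,
)

_BETA_EPS = 1e-6  # keep emitted values strictly inside (0, 1)


@dataclass(frozen=True)
class PlantedModule:
    """A latent co-methylated module planted in one or more datasets.

    tumor_shift moves the module's latent mean in tumor samples only, so a
    positive shift reads as tumor-hypermethylation of the whole module.
    ``bimodal_factor`` makes the per-sample factor a two-component mixture
    (the X-inactivation-like internal control); ``chromosome`` overrides
    the annotated chromosome of the module's probes.
    """

    name: str
    size: int
    loading_range: tuple[float, float] = (0.55, 0.75)
    baseline_mu: float = 0.0
    tumor_shift: float = 0.0
    presence: frozenset[int] = frozenset({0})
    bimodal_factor: bool = False
    chromosome: str | None = None

    def __post_init__(self):
        if self.size < 2:
            raise ConfigurationError(f"module {self.name!r}: size must be >= 2")
        lo, hi = self.loading_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"module {self.name!r}: loading_range must be in (0, inf)")
        if not self.presence:
            raise ConfigurationError(f"module {self.name!r}: presence must be non-empty")
        object.__setattr__(self, "presence", frozenset(int(d) for d in self.presence))


@dataclass(frozen=True)
class SimConfig:
    n_datasets: int = 6
    probes_per_dataset: int = 1500
    samples_per_dataset: int = 120
    normal_fraction: float = 0.25
    shared_modules: tuple[PlantedModule, ...] = ()
    specific_modules: tuple[tuple[int, PlantedModule], ...] = ()
    noise_sd: float = 0.4
    seed: int = 0
    multi_gene_fraction: float = 0.05
    background_mean_range: tuple[float, float] = (-2.5, 2.5)
    background_sd_range: tuple[float, float] = (0.3, 1.0)

    def __post_init__(self):
        if min(self.n_datasets, self.probes_per_dataset, self.samples_per_dataset) <= 0:
            raise ConfigurationError("all counts must be positive")
        if not (0 <= self.normal_fraction <= 1):
            raise ConfigurationError("normal_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for d, _m in self.specific_modules:
            if not (0 <= d < self.n_datasets):
                raise ConfigurationError(f"specific module dataset index {d} out of range")
        for m in self.shared_modules:
            for d in m.presence:
                if not (0 <= d < self.n_datasets):
                    raise ConfigurationError(
                        f"module {m.name!r} presence index {d} out of range"
                    )
        total = sum(m.size for m in self.all_modules())
        if total > self.probes_per_dataset:
            raise ConfigurationError(
                f"module sizes total {total} exceed the probe budget "
                f"({self.probes_per_dataset})"
            )

    def all_modules(self) -> list[PlantedModule]:
        """Shared modules followed by dataset-specific ones (presence set to
        the owning dataset)."""
        mods = list(self.shared_modules)
        for d, m in self.specific_modules:
            mods.append(
                PlantedModule(
                    name=m.name, size=m.size, loading_range=m.loading_range,
                    baseline_mu=m.baseline_mu, tumor_shift=m.tumor_shift,
                    presence=frozenset({d}), bimodal_factor=m.bimodal_factor,
                    chromosome=m.chromosome,
                )
            )
        return mods


@dataclass(frozen=True)
class ModuleTruth:
    name: str
    probe_ids: tuple[str, ...]
    presence: frozenset[int]
    tumor_shift: float

    @property
    def probe_set(self) -> frozenset[str]:
        return frozenset(self.probe_ids)

    def pairs(self) -> set[tuple[str, str]]:
        ids = sorted(self.probe_ids)
        return {
            (ids[i], ids[j])
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        }


@dataclass
class GroundTruth:
    """Planted module memberships per dataset."""

    modules: list[ModuleTruth]

    def module(self, name: str) -> ModuleTruth:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)

    def modules_in_dataset(self, d: int) -> list[ModuleTruth]:
        return [m for m in self.modules if d in m.presence]


@dataclass
class Study:
    """One generated multi-dataset study."""

    config: SimConfig
    labels: list[str]
    betas: list[BetaMatrix]
    sheets: list[SampleSheet]
    annotation: ProbeAnnotation
    truth: GroundTruth


def default_study_config(seed: int = 0) -> SimConfig:
    """The reference study: 6 datasets x 1,500 probes x 120 samples (25%
    normal), three shared modules of size 30 planted in 4 of 6 datasets
    (tumor shifts +2, -2 and 0), two dataset-specific modules of size 30,
    latent noise sd 0.4."""
    # the hypomethylated-in-tumor module starts heavily methylated (high
    # latent baseline), mirroring a module demethylated in tumors; the
    # hypermethylated-in-tumor module starts at mid methylation
    shared = tuple(
        PlantedModule(
            name=name, size=30, tumor_shift=shift, baseline_mu=mu,
            presence=frozenset({0, 1, 2, 3}),
        )
        for name, shift, mu in (
            ("shared_hyper", 2.0, 0.0),
            ("shared_hypo", -2.0, 2.0),
            ("shared_null", 0.0, 0.0),
        )
    )
    specific = (
        (4, PlantedModule(name="specific_d4", size=30)),
        (5, PlantedModule(name="specific_d5", size=30)),
    )
    return SimConfig(shared_modules=shared, specific_modules=specific, seed=seed)


def _chromosome_cycle():
    return [f"chr{i}" for i in range(1, 23)]


def generate_study(config: SimConfig) -> Study:
    """Generate beta matrices, sample sheets, annotation and ground truth."""
    P = config.probes_per_dataset
    N = config.samples_per_dataset
    modules = config.all_modules()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(2 + config.n_datasets)
    module_rng = np.random.default_rng(streams[0])
    probe_rng = np.random.default_rng(streams[1])

    # probe namespace shared by all datasets; modules occupy leading blocks
    probe_ids = [f"cg{i:07d}" for i in range(1, P + 1)]
    cursor = 0
    module_rows: list[np.ndarray] = []
    for m in modules:
        module_rows.append(np.arange(cursor, cursor + m.size))
        cursor += m.size

    loadings = [
        module_rng.uniform(m.loading_range[0], m.loading_range[1], size=m.size)
        for m in modules
    ]

    # background latent parameters are probe properties, shared across datasets
    bg_mu = probe_rng.uniform(*config.background_mean_range, size=P)
    bg_sd = probe_rng.uniform(*config.background_sd_range, size=P)

    # annotation: 1:1 synthetic gene symbols, a fraction annotated as
    # semicolon-joined gene families; module probes share one chromosome
    chroms = np.array(
        [_chromosome_cycle()[i] for i in probe_rng.integers(0, 22, size=P)], dtype=object
    )
    cycle = _chromosome_cycle()
    for k, (m, rows) in enumerate(zip(modules, module_rows)):
        chroms[rows] = m.chromosome if m.chromosome else cycle[k % len(cycle)]
    family = probe_rng.random(P) < config.multi_gene_fraction
    gene_symbols = []
    for i in range(P):
        main = f"G{i + 1:05d}"
        gene_symbols.append((main, f"{main}L") if family[i] else (main,))
    annotation = ProbeAnnotation(list(probe_ids), gene_symbols, list(chroms))

    n_normal = int(round(config.normal_fraction * N))
    labels, betas, sheets = [], [], []
    truth_presence: dict[str, set[int]] = {m.name: set() for m in modules}

    for d in range(config.n_datasets):
        rng = np.random.default_rng(streams[2 + d])
        label = f"D{d}"
        sample_ids = [f"{label}S{j:03d}" for j in range(1, N + 1)]
        groups = ["normal"] * n_normal + ["tumor"] * (N - n_normal)
        ages = np.clip(np.round(rng.normal(60.0, 10.0, size=N), 1), 25.0, 95.0)
        tumor_ind = np.array([g == "tumor" for g in groups], dtype=float)

        latent = bg_mu[:, None] + bg_sd[:, None] * rng.standard_normal((P, N))
        for m, rows, load in zip(modules, module_rows, loadings):
            if d not in m.presence:
                continue  # the module's probes behave as background here
            truth_presence[m.name].add(d)
            if m.bimodal_factor:
                comp = rng.integers(0, 2, size=N) * 2 - 1
                f = comp * 1.5 + 0.3 * rng.standard_normal(N)
            else:
                f = rng.standard_normal(N)
            eps = config.noise_sd * rng.standard_normal((m.size, N))
            latent[rows] = (
                m.baseline_mu
                + m.tumor_shift * tumor_ind[None, :]
                + np.outer(load, f)
                + eps
            )
        beta = np.clip(expit(latent), _BETA_EPS, 1.0 - _BETA_EPS)
        labels.append(label)
        betas.append(BetaMatrix(list(probe_ids), sample_ids, beta))
        sheets.append(SampleSheet(sample_ids, groups, ages))

    truth = GroundTruth(
        [
            ModuleTruth(
                name=m.name,
                probe_ids=tuple(probe_ids[i] for i in rows),
                presence=frozenset(truth_presence[m.name]),
                tumor_shift=m.tumor_shift,
            )
            for m, rows in zip(modules, module_rows)
        ]
    )
    return Study(config, labels, betas, sheets, annotation, truth)


def write_fixture(study: Study, directory) -> dict[str, Path]:
    """Write the study as the TSV formats the readers consume.

    Emits one beta matrix and one sample sheet per dataset, a single probe
    annotation, and the ground truth as JSON.  Beta values round-trip to 6
    decimal places.
    """
    if not study.betas:
        raise DataError("write_fixture: study contains no datasets")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for label, bm, sheet in zip(study.labels, study.betas, study.sheets):
        paths[f"beta_{label}"] = write_beta_matrix(bm, directory / f"{label}_beta.tsv")
        paths[f"samples_{label}"] = write_sample_sheet(
            sheet, directory / f"{label}_samples.tsv"
        )
    paths["annotation"] = write_probe_annotation(
        study.annotation, directory / "probe_annotation.tsv"
    )
    truth_json = {
        m.name: {
            "probe_ids": list(m.probe_ids),
            "presence": sorted(m.presence),
            "tumor_shift": m.tumor_shift,
        }
        for m in study.truth.modules
    }
    truth_path = directory / "ground_truth.json"
    truth_path.write_text(json.dumps(truth_json, indent=1))
    paths["ground_truth"] = truth_path
    return paths


def config_from_json(obj: dict) -> SimConfig:
    """Build a SimConfig from a JSON-style dict (CLI ``simulate --config``)."""

    def module_from(mobj: dict) -> PlantedModule:
        kwargs = dict(mobj)
        if "loading_range" in kwargs:
            kwargs["loading_range"] = tuple(kwargs["loading_range"])
        if "presence" in kwargs:
            kwargs["presence"] = frozenset(kwargs["presence"])
        return PlantedModule(**kwargs)

    kwargs = dict(obj)
    kwargs["shared_modules"] = tuple(
        module_from(m) for m in kwargs.get("shared_modules", [])
    )
    kwargs["specific_modules"] = tuple(
        (int(d), module_from(m)) for d, m in kwargs.get("specific_modules", [])
    )
    for key in ("background_mean_range", "background_sd_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SimConfig(**kwargs)
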