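"""Core data containers and delimited-text readers/writers.

Beta matrices are probe x sample tables of methylation beta values (the
methylated fraction of signal at a CpG probe, bounded in [0, 1]).  All
formats are plain TSV:

* beta matrix   -- first column probe id, header row sample ids, empty cell
  means missing;
* sample sheet  -- columns ``sample_id  group  age`` with group in
  {tumor, normal} and age optional;
* probe annotation -- columns ``probe_id  gene_symbols  chromosome`` with
  gene symbols semicolon-delimited (first symbol is the canonical gene for
  multi-gene "family" probes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError

logger = logging.getLogger("panmethyl")

VALID_GROUPS = ("tumor", "normal")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise DataError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class BetaMatrix:
    """Probe x sample matrix of beta values; NaN marks a missing cell."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise DataError(
                f"beta matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        bad = np.argwhere((self.values < 0) | (self.values > 1))
        if bad.size:
            i, j = bad[0]
            raise DataError(
                f"beta value {self.values[i, j]!r} outside [0, 1] at "
                f"probe {self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probe_ids)}

    def select_probes(self, keep) -> "BetaMatrix":
        """Return a copy restricted to the given boolean mask or probe-id list."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            index = self.probe_index()
            idx = np.array([index[p] for p in keep], dtype=int)
        return BetaMatrix(
            [self.probe_ids[i] for i in idx], list(self.sample_ids), self.values[idx].copy()
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))


@dataclass
class SampleSheet:
    """Per-sample tumor/normal labels and (optional) ages for one dataset."""

    sample_ids: list[str]
    groups: list[str]
    ages: np.ndarray = field(default=None)

    def __post_init__(self):
        _check_unique(self.sample_ids, "sample")
        if len(self.groups) != len(self.sample_ids):
            raise DataError("sample sheet: groups and sample_ids differ in length")
        for sid, g in zip(self.sample_ids, self.groups):
            if g not in VALID_GROUPS:
                raise DataError(f"sample {sid!r}: group must be one of {VALID_GROUPS}, got {g!r}")
        if self.ages is None:
            self.ages = np.full(len(self.sample_ids), np.nan)
        self.ages = np.asarray(self.ages, dtype=float)
        if self.ages.shape != (len(self.sample_ids),):
            raise DataError("sample sheet: ages length mismatch")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def aligned_to(self, sample_ids: list[str]) -> "SampleSheet":
        """Reorder/restrict to the given sample ids (they must all be present)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise DataError(f"sample sheet missing samples: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return SampleSheet(
            list(sample_ids), [self.groups[i] for i in idx], self.ages[np.array(idx)]
        )

    def group_values(self, values: np.ndarray, group: str) -> np.ndarray:
        mask = np.array([g == group for g in self.groups])
        return np.asarray(values)[mask]


@dataclass
class ProbeAnnotation:
    """Probe id -> (ordered gene symbols, chromosome)."""

    probe_ids: list[str]
    gene_symbols: list[tuple[str, ...]]
    chromosomes: list[str]

    def __post_init__(self):
        _check_unique(self.probe_ids, "probe")
        if not (len(self.probe_ids) == len(self.gene_symbols) == len(self.chromosomes)):
            raise DataError("probe annotation: column length mismatch")
        self._map = {
            p: (g, c)
            for p, g, c in zip(self.probe_ids, self.gene_symbols, self.chromosomes)
        }

    def genes_for(self, probe_id: str) -> tuple[str, ...] | None:
        entry = self._map.get(probe_id)
        return entry[0] if entry else None

    def chromosome_for(self, probe_id: str) -> str | None:
        entry = self._map.get(probe_id)
        return entry[1] if entry else None


# ---------------------------------------------------------------------------
# readers


def read_beta_matrix(path) -> BetaMatrix:
    """Parse a TSV beta matrix.

    Empty cells parse as missing (NaN); non-numeric cells and values outside
    [0, 1] raise :class:`DataError` naming the offending probe and sample.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.name is None and df.columns.size == 0:
        raise DataError(f"{path}: malformed header")
    probe_ids = [str(p) for p in df.index]
    # pandas silently renames duplicate header fields; check the raw header
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = [str(s) for s in header[1:]]
    if len(sample_ids) != df.shape[1]:
        raise DataError(f"{path}: malformed header (field count mismatch)")
    _check_unique(sample_ids, "sample")
    _check_unique(probe_ids, "probe")

    raw = df.to_numpy(dtype=object)
    flat = pd.to_numeric(pd.Series(raw.ravel()), errors="coerce").to_numpy()
    nonempty = np.array([str(x).strip() != "" for x in raw.ravel()])
    bad = np.flatnonzero(np.isnan(flat) & nonempty)
    if bad.size:
        i, j = divmod(int(bad[0]), df.shape[1])
        raise DataError(
            f"{path}: non-numeric cell {raw[i, j]!r} at probe {probe_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    values = flat.reshape(raw.shape)
    return BetaMatrix(probe_ids, sample_ids, values)


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise DataError(f"{path}: sample sheet missing column {col!r}")
    ages = (
        pd.to_numeric(df["age"], errors="coerce").to_numpy()
        if "age" in df.columns
        else np.full(len(df), np.nan)
    )
    return SampleSheet(list(df["sample_id"]), list(df["group"]), ages)


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("probe_id", "gene_symbols", "chromosome"):
        if col not in df.columns:
            raise DataError(f"{path}: probe annotation missing column {col!r}")
    genes = [
        tuple(g for g in str(s).split(";") if g) for s in df["gene_symbols"]
    ]
    return ProbeAnnotation(list(df["probe_id"]), genes, list(df["chromosome"]))


# ---------------------------------------------------------------------------
# writers


def write_beta_matrix(bm: BetaMatrix, path, float_format: str = "%.6f") -> Path:
    path = Path(path)
    bm.to_dataframe().to_csv(
        path, sep="\t", float_format=float_format, na_rep="", index_label="probe_id"
    )
    return path


def write_sample_sheet(sheet: SampleSheet, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample_id": sheet.sample_ids,
            "group": sheet.groups,
            "age": ["" if np.isnan(a) else f"{a:g}" for a in sheet.ages],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def write_probe_annotation(ann: ProbeAnnotation, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "probe_id": ann.probe_ids,
            "gene_symbols": [";".join(g) for g in ann.gene_symbols],
            "chromosome": ann.chromosomes,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path
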