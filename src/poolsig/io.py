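"""File formats, containers and pipeline configuration.

Expression matrices travel as tab-separated text: an optional leading
comment line ``# scale=<tag> level=<probe|gene>``, then a header row of
sample ids with the feature-id column first.  Clinical tables are CSV with
a fixed column inventory.  Everything round-trips losslessly so that every
pipeline stage can be re-run from its written artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SCALE_TAGS = ("raw-linear", "log2", "z", "qnorm")

#: mandatory clinical columns, in canonical order
CLINICAL_COLUMNS = [
    "sample_id",
    "cohort",
    "age",
    "tumor_size",
    "grade",
    "er_status",
    "node_status",
    "relapse_event",
    "time_years",
]


class FormatError(ValueError):
    """Malformed input file (carries a human-readable location)."""


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix with an explicit scale tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by probe/gene id, columns by sample id.
    scale : str
        One of ``raw-linear``, ``log2``, ``z``, ``qnorm``.
    level : str
        ``probe`` or ``gene``.
    """

    values: pd.DataFrame
    scale: str
    level: str = "probe"

    def __post_init__(self) -> None:
        if self.scale not in SCALE_TAGS:
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.level not in ("probe", "gene"):
            raise ValueError(f"unknown level {self.level!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.scale == "raw-linear" and (arr <= 0).any():
            r, c = np.argwhere(arr <= 0)[0]
            raise ValueError(
                "raw-linear matrix has non-positive value at "
                f"feature {idx[r]!r}, sample {cols[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.scale, self.level)


@dataclass
class CohortBundle:
    """One cohort's expression matrix, clinical table and provenance."""

    cohort_id: str
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    transforms: list[str] = field(default_factory=list)
    affine_params: tuple | None = None  # (a, b) linking stored values to log2

    def record(self, step: str) -> None:
        self.transforms.append(step)


def write_expression(m: ExpressionMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# scale={m.scale} level={m.level}\n")
        m.values.to_csv(fh, sep="\t", index_label="feature_id")


def read_expression(path) -> ExpressionMatrix:
    """Read a TSV expression matrix, validating ids and cell contents."""
    path = Path(path)
    scale, level = "log2", "probe"
    with open(path) as fh:
        first = fh.readline()
        offset = 0
        if first.startswith("#"):
            offset = 1
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                if k == "scale":
                    scale = v
                elif k == "level":
                    level = v
        else:
            fh.seek(0)
        header_pos = fh.tell()
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError(f"{path}: duplicate sample ids")
        fh.seek(header_pos)
        try:
            df = pd.read_csv(fh, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
        df.index.name = None
    for j, col in enumerate(df.columns):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0]
            line = df.index.get_loc(row) + 2 + offset
            raise FormatError(
                f"{path}: non-numeric cell at line {line}, column {col!r} "
                f"(feature {row!r})"
            )
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate feature ids")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids")
    return ExpressionMatrix(df, scale=scale, level=level)


def write_clinical(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_clinical(path) -> pd.DataFrame:
    """Read and type-check a clinical CSV table.

    Missing values stay missing (NaN); unknown extra columns are kept.
    ``relapse_event`` must be 0, 1 or missing.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    for col in ("age", "tumor_size", "time_years"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("grade", "er_status", "node_status", "relapse_event"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype("Float64")
    bad = df["relapse_event"].dropna()
    if not bad.isin([0, 1]).all():
        raise FormatError(f"{path}: relapse_event outside {{0, 1, missing}}")
    return df


def write_probe_map(probe_map: pd.DataFrame, path) -> None:
    probe_map.to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["probe_id", "gene_id"]:
        raise FormatError(f"{path}: expected columns probe_id, gene_id")
    return df


@dataclass
class PipelineConfig:
    """Every stage parameter of the end-to-end pipeline, with one seed.

    All stage seeds are derived deterministically from ``seed`` so two runs
    with equal configs are bit-identical.
    """

    seed: int = 0
    # synthetic cohorts (see simulate.SimConfig for semantics)
    sim: dict = field(default_factory=dict)
    # harmonization
    reference: int = 0
    params: str = "given"  # given | estimate
    # gene ranking
    subsample: int = 200
    bootstrap_rounds: int = 200
    trim: float = 0.05
    top_genes: int = 100
    # model suite
    split_sizes: tuple[int, int] | None = None  # None -> 370:387 proportions
    split_rounds: int = 400
    cv_sets: int = 20
    models: tuple[str, ...] = ("dt", "lr", "ann80", "ann100", "dl", "da80", "da100")
    # signature
    k_max: int = 100
    min_sensitivity: float = 0.80

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["split_sizes"] = list(self.split_sizes) if self.split_sizes else None
        d["models"] = list(self.models)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("split_sizes") is not None:
            d["split_sizes"] = tuple(d["split_sizes"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


def file_checksum(path) -> str:
    """SHA-256 of a file, for stage provenance logs."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
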