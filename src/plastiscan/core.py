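"""Core domain types, file I/O and design validation.

The analysis operates on two bulk RNA-seq experiments run on the same four
populations (two coast/mine ecotype pairs): a *salt* experiment
(control + 0.1 M NaCl) and a *zinc* experiment (control + zinc). Counts are
genes x samples integer matrices; the sample sheet records population,
ecotype, pair, individual, treatment and experiment for every sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

POPULATIONS = ("Coast-W", "Mine-W", "Coast-E", "Mine-E")
ECOTYPES = ("coast", "mine")
PAIRS = ("W", "E")
TREATMENTS = ("control", "salt", "zinc")
EXPERIMENTS = ("salt_expt", "zinc_expt")

#: cue treatment belonging to each experiment
EXPERIMENT_CUE = {"salt_expt": "salt", "zinc_expt": "zinc"}

SHEET_COLUMNS = [
    "sample_id",
    "population",
    "ecotype",
    "pair",
    "individual",
    "treatment",
    "experiment",
]


class FormatError(ValueError):
    """Malformed input table (negative counts, duplicate ids, bad header)."""


class ConsistencyError(ValueError):
    """Count matrix and sample sheet disagree."""


@dataclass
class CountMatrix:
    """Non-negative integer expression counts, genes in rows, samples in columns.

    ``counts`` is a pandas DataFrame indexed by gene id with sample ids as
    columns. Validation enforces uniqueness, integrality and non-negativity.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[0] < 2 or c.shape[1] < 2:
            raise FormatError(
                f"count matrix needs >=2 genes and >=2 samples, got {c.shape}"
            )
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if c.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        if not all(np.issubdtype(dt, np.integer) for dt in c.dtypes):
            # accept floats that are exactly integral (as written by e.g. R)
            vals = c.to_numpy()
            if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
                raise FormatError("counts must be integers")
            self.counts = c.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts present")
        self.counts.index.name = "gene_id"

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)])

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(samples)])


def validate_sheet(sheet: pd.DataFrame, cm: CountMatrix | None = None) -> pd.DataFrame:
    """Validate a sample sheet, optionally cross-checking against a matrix.

    Enforces: required columns present; sample ids unique; treatment levels
    consistent with the experiment (salt only in the salt experiment, zinc
    only in the zinc experiment); every matrix column described exactly once.
    """
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    sheet = sheet[SHEET_COLUMNS].copy()
    if sheet["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sheet")
    bad_pop = set(sheet["population"]) - set(POPULATIONS)
    if bad_pop:
        raise FormatError(f"unknown populations: {sorted(bad_pop)}")
    for expt, cue in EXPERIMENT_CUE.items():
        sub = sheet[sheet["experiment"] == expt]
        bad = set(sub["treatment"]) - {"control", cue}
        if bad:
            raise ConsistencyError(
                f"treatment(s) {sorted(bad)} not allowed in {expt}"
            )
    if cm is not None:
        sheet_ids = set(sheet["sample_id"])
        matrix_ids = set(cm.sample_ids)
        orphan = matrix_ids - sheet_ids
        if orphan:
            raise ConsistencyError(
                f"samples in matrix but not in sheet: {sorted(orphan)}"
            )
    return sheet


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def read_experiment(counts_path, sheet_path) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a counts TSV/CSV (first column gene_id) and its sample sheet."""
    counts_path, sheet_path = Path(counts_path), Path(sheet_path)
    raw = _read_table(counts_path)
    if raw.shape[1] < 2:
        raise FormatError(f"{counts_path}: no sample columns found")
    cm = CountMatrix(raw.set_index(raw.columns[0]))
    sheet = validate_sheet(_read_table(sheet_path), cm)
    # keep only sheet rows for samples in this matrix, in matrix column order
    sheet = (
        sheet.set_index("sample_id")
        .loc[cm.sample_ids]
        .reset_index(names="sample_id")
    )
    return cm, sheet


def low_count_filter(
    cm: CountMatrix, min_count: int = 10, mode: str = "any_sample"
) -> CountMatrix:
    """Drop weakly covered genes.

    mode="any_sample" (default): a gene is removed if ANY sample count falls
    below ``min_count`` — the stricter reading that keeps matrices
    rectangular. mode="total": remove genes whose summed count across samples
    is below ``min_count``.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if mode == "any_sample":
        keep = (cm.counts >= min_count).all(axis=1)
    elif mode == "total":
        keep = cm.counts.sum(axis=1) >= min_count
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    if not keep.any():
        raise ValueError("low_count_filter removed every gene")
    return CountMatrix(cm.counts.loc[keep])


@dataclass
class AnalysisConfig:
    """Knobs shared by the whole pipeline.

    alpha: significance level for adjusted p-values (both DE calls and the
    P_ST/F_ST exceedance quantile). min_count: per-sample count floor for the
    low-count filter. c_over_h2: the c/h^2 scalar in P_ST.
    """

    alpha: float = 0.05
    min_count: int = 10
    n_permutations: int = 10_000
    bootstrap_reps: int = 1000
    c_over_h2: float = 1.0
    seed: int = 0
    filter_mode: str = "any_sample"
    comparability_mode: str = "per_population"
    paired_plasticity: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.c_over_h2 <= 0:
            raise ValueError("c_over_h2 must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FstDistribution:
    """Genome-wide neutral differentiation values for one population pair."""

    pair: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("FstDistribution must be non-empty")
        if np.any((v < 0) | (v > 1)) or not np.all(np.isfinite(v)):
            raise ValueError("F_ST values must lie in [0, 1]")
        self.values = v

    @classmethod
    def read_tsv(cls, path, pair: str) -> "FstDistribution":
        vals = pd.read_csv(path, sep="\t").iloc[:, 0].to_numpy()
        return cls(pair=pair, values=vals)


_FLOAT_FMT = "%.12g"  # round-trip to 12 significant digits


def write_results(tables: dict[str, pd.DataFrame], out_dir, metadata: dict | None = None) -> dict:
    """Write one TSV per named table plus a YAML run-metadata file.

    Returns a manifest mapping table name to the written path. Missing values
    are written as "NA"; floats carry 12 significant digits.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, tab in tables.items():
        path = out_dir / f"{name}.tsv"
        tab.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)
        manifest[name] = str(path)
    if metadata is not None:
        meta_path = out_dir / "run_metadata.yaml"
        with open(meta_path, "w") as fh:
            yaml.safe_dump(metadata, fh, sort_keys=True)
        manifest["run_metadata"] = str(meta_path)
    return manifest


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
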