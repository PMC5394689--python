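"""Domain types, TSV readers, and JSON serialization of result objects.

On-disk conventions
-------------------
* counts TSV: first column ``gene_id``, remaining columns one per sample;
  UTF-8, tab-delimited, no quoting.
* metadata TSV columns: ``sample_id, omics_kind, growth_phase,
  carbon_source, na_mM, mg_mM, batch, replicate, time_h`` (``time_h``
  optional).
* growth TSV columns: ``replicate_id, condition_id, time_min, od600``.
* flux TSV columns: ``sample_id, condition_id, replicate, na_mM, mg_mM,
  ratio_name, value`` plus optional ``doubling_time_min``.
* results are JSON objects carrying ``schema_version`` and a ``type`` tag;
  non-finite floats are serialized as ``null`` alongside an explicit
  undefined flag on the owning object.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from omiclust.errors import ValidationError

SCHEMA_VERSION = 1

OMICS_KINDS = ("mrna", "protein")
GROWTH_PHASES = ("exponential", "stationary", "late_stationary")
CARBON_SOURCES = ("glucose", "glycerol", "lactate", "gluconate")

#: Branch-point labels of the 13 measured flux ratios.  Users may supply
#: their own vocabulary when reading a flux table.
DEFAULT_FLUX_RATIO_NAMES = (
    "serine_from_glycolysis",
    "glycine_from_serine",
    "pyruvate_from_ed_pathway",
    "pyruvate_from_malate_upper_bound",
    "pyruvate_from_malate_lower_bound",
    "oaa_from_pep",
    "oaa_from_glyoxylate",
    "pep_from_oaa",
    "p5p_from_g6p",
    "e4p_from_p5p",
    "s7p_from_transketolase",
    "acetyl_coa_from_pyruvate",
    "co2_from_formate",
)

METADATA_COLUMNS = (
    "sample_id",
    "omics_kind",
    "growth_phase",
    "carbon_source",
    "na_mM",
    "mg_mM",
    "batch",
    "replicate",
)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class CountMatrix:
    """Nonnegative integer gene-by-sample count table."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # (n_genes, n_samples) integer
    omics_kind: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        counts = np.asarray(self.counts)
        if self.omics_kind not in OMICS_KINDS:
            raise ValidationError(
                f"omics_kind must be one of {OMICS_KINDS}, got {self.omics_kind!r}"
            )
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)):
                raise ValidationError("counts contain non-finite values")
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                g, s = np.argwhere(rounded != counts)[0]
                raise ValidationError(
                    f"non-integral count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}: {counts[g, s]}"
                )
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            g, s = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}: {counts[g, s]}"
            )
        object.__setattr__(self, "counts", counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and self.omics_kind == other.omics_kind
            and np.array_equal(self.counts, other.counts)
        )

    __hash__ = None  # type: ignore[assignment]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class SampleTable:
    """Validated per-sample experimental annotations."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        _check_unique(df["sample_id"].astype(str).tolist(), "sample")
        bad_phase = set(df["growth_phase"]) - set(GROWTH_PHASES)
        if bad_phase:
            raise ValidationError(
                f"unknown growth_phase values {sorted(bad_phase)}; "
                f"allowed: {GROWTH_PHASES}"
            )
        bad_carbon = set(df["carbon_source"]) - set(CARBON_SOURCES)
        if bad_carbon:
            raise ValidationError(
                f"unknown carbon_source values {sorted(bad_carbon)}; "
                f"allowed: {CARBON_SOURCES}"
            )
        bad_omics = set(df["omics_kind"]) - set(OMICS_KINDS)
        if bad_omics:
            raise ValidationError(
                f"unknown omics_kind values {sorted(bad_omics)}; allowed: {OMICS_KINDS}"
            )
        for col in ("na_mM", "mg_mM"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any() or (vals <= 0).any():
                bad = df.loc[vals.isna() | (vals <= 0), "sample_id"].tolist()
                raise ValidationError(f"{col} must be > 0 for samples {bad}")
            df[col] = vals.astype(float)
        if "time_h" not in df.columns:
            df["time_h"] = np.nan
        df = df.reset_index(drop=True)
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data["sample_id"].astype(str))

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleTable":
        """Return a copy with rows reordered to match ``sample_ids``."""
        idx = self.data.set_index("sample_id")
        missing = [s for s in sample_ids if s not in idx.index]
        if missing:
            raise ValidationError(f"metadata missing samples: {missing}")
        out = idx.loc[list(sample_ids)].reset_index()
        return SampleTable(out)

    def check_matches(self, matrix: CountMatrix) -> None:
        """Require the sample id sets of table and matrix to be identical."""
        table_ids = set(self.sample_ids)
        matrix_ids = set(matrix.sample_ids)
        extra = sorted(table_ids - matrix_ids)
        orphans = sorted(matrix_ids - table_ids)
        if extra or orphans:
            parts = []
            if extra:
                parts.append(f"metadata-only ids: {extra}")
            if orphans:
                parts.append(f"matrix-only ids: {orphans}")
            raise ValidationError("sample id mismatch; " + "; ".join(parts))


@dataclass(frozen=True)
class GrowthCurve:
    """Timed OD600 readings for one replicate culture."""

    replicate_id: str
    condition_id: str
    time_min: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.shape != od.shape or t.ndim != 1:
            raise ValidationError("time_min and od600 must be 1-D of equal length")
        if len(t) < 4:
            raise ValidationError(
                f"growth curve {self.condition_id}/{self.replicate_id} has "
                f"{len(t)} points; at least 4 required"
            )
        if not np.all(np.diff(t) > 0):
            raise ValidationError("time_min must be strictly increasing")
        if not np.all(od > 0):
            raise ValidationError("od600 readings must be positive")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "od600", od)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrowthCurve):
            return NotImplemented
        return (
            self.replicate_id == other.replicate_id
            and self.condition_id == other.condition_id
            and np.array_equal(self.time_min, other.time_min)
            and np.array_equal(self.od600, other.od600)
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class FluxRatioTable:
    """Long-format table of branch-point flux ratios per sample."""

    data: pd.DataFrame
    ratio_names: tuple[str, ...] = DEFAULT_FLUX_RATIO_NAMES

    def __post_init__(self) -> None:
        df = self.data.copy().reset_index(drop=True)
        required = ("sample_id", "condition_id", "replicate", "na_mM", "mg_mM",
                    "ratio_name", "value")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"flux table missing columns: {missing}")
        vals = pd.to_numeric(df["value"], errors="coerce")
        if vals.isna().any() or (vals < 0).any() or (vals > 1).any():
            bad = df.loc[vals.isna() | (vals < 0) | (vals > 1)].index.tolist()
            raise ValidationError(f"flux values outside [0, 1] at rows {bad}")
        df["value"] = vals.astype(float)
        unknown = set(df["ratio_name"]) - set(self.ratio_names)
        if unknown:
            raise ValidationError(
                f"unknown ratio_name values {sorted(unknown)}; "
                f"declared vocabulary: {list(self.ratio_names)}"
            )
        object.__setattr__(self, "data", df)
        object.__setattr__(self, "ratio_names", tuple(self.ratio_names))


# ---------------------------------------------------------------------------
# readers


def _round_half_away(values: np.ndarray) -> np.ndarray:
    """Round half away from zero (np.rint rounds half to even)."""
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


def read_count_matrix(path: str | Path, omics_kind: str) -> CountMatrix:
    """Read a gene-by-sample counts TSV.

    Protein counts may be fractional (shared peptide spectra); they are
    rounded half-away-from-zero and blank cells become 0.  mRNA counts must
    already be integral.
    """
    if omics_kind not in OMICS_KINDS:
        raise ValidationError(f"omics_kind must be one of {OMICS_KINDS}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    blank = df.isna() | (df == "")
    unparsable = np.isnan(values) & ~blank.to_numpy()
    if unparsable.any():
        g, s = np.argwhere(unparsable)[0]
        raise ValidationError(
            f"non-numeric cell at gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
        )
    values = np.where(np.isnan(values), 0.0, values)
    if np.any(values < 0):
        g, s = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative count at gene {gene_ids[g]!r}, sample {sample_ids[s]!r}: "
            f"{values[g, s]}"
        )
    if omics_kind == "protein":
        counts = _round_half_away(values).astype(np.int64)
    else:
        rounded = np.rint(values)
        if not np.array_equal(rounded, values):
            g, s = np.argwhere(rounded != values)[0]
            raise ValidationError(
                f"non-integral mRNA count at gene {gene_ids[g]!r}, "
                f"sample {sample_ids[s]!r}: {values[g, s]}"
            )
        counts = values.astype(np.int64)
    return CountMatrix(tuple(gene_ids), tuple(sample_ids), counts, omics_kind)


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    frame = m.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")


def read_sample_table(
    path: str | Path, matrix: CountMatrix | None = None
) -> SampleTable:
    """Read and validate the metadata TSV; optionally cross-check a matrix."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str,
                                            "replicate": str})
    table = SampleTable(df)
    if matrix is not None:
        table.check_matches(matrix)
    return table


def write_sample_table(t: SampleTable, path: str | Path) -> None:
    t.data.to_csv(path, sep="\t", index=False)


def read_growth_curves(path: str | Path) -> list[GrowthCurve]:
    """Read growth TSV; one curve per (condition_id, replicate_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"replicate_id": str,
                                            "condition_id": str})
    required = ("replicate_id", "condition_id", "time_min", "od600")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"growth table missing columns: {missing}")
    curves = []
    for (cond, rep), grp in df.groupby(["condition_id", "replicate_id"], sort=True):
        grp = grp.sort_values("time_min")
        curves.append(
            GrowthCurve(
                replicate_id=str(rep),
                condition_id=str(cond),
                time_min=grp["time_min"].to_numpy(dtype=float),
                od600=grp["od600"].to_numpy(dtype=float),
            )
        )
    return curves


def write_growth_curves(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.time_min, c.od600):
            rows.append(
                {"replicate_id": c.replicate_id, "condition_id": c.condition_id,
                 "time_min": t, "od600": od}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_flux_table(
    path: str | Path, ratio_names: Sequence[str] = DEFAULT_FLUX_RATIO_NAMES
) -> FluxRatioTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition_id": str,
                                            "replicate": str, "ratio_name": str})
    return FluxRatioTable(df, tuple(ratio_names))


def write_flux_table(t: FluxRatioTable, path: str | Path) -> None:
    t.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result objects and JSON round-trip


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample median-of-ratios scaling constants."""

    sample_ids: tuple[str, ...]
    factors: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "factors", tuple(float(f) for f in self.factors))
        if len(self.sample_ids) != len(self.factors):
            raise ValidationError("sample_ids and factors differ in length")
        for s, f in zip(self.sample_ids, self.factors):
            if not math.isfinite(f) or f <= 0:
                raise ValidationError(f"size factor for sample {s!r} is {f}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.sample_ids, self.factors))


@dataclass(frozen=True)
class QCReport:
    """Replicate-consistency summary for one sample pair."""

    sample_a: str
    sample_b: str
    n_genes_used: int
    median_log2_diff: float
    iqr_log2_diff: float
    skewness: float
    flag_threshold: float
    flagged: bool
    note: str = ""


@dataclass(frozen=True)
class ClusterSignificanceResult:
    """Permutation z-score for one (variable, level) combination."""

    variable_name: str
    level: str  # a level name or "overall"
    observed_mean: float
    null_mean: float
    null_sd: float
    z: float | None
    undefined: bool
    n_pairs: int
    n_samples: int
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if self.undefined:
            object.__setattr__(self, "z", None)
        elif self.z is None or not math.isfinite(self.z):
            raise ValidationError("finite z required unless undefined flag is set")


@dataclass(frozen=True)
class DoublingTimeEstimate:
    """Replicate doubling times with mean and 95% t-interval."""

    condition_id: str
    per_replicate_min: tuple[float, ...]
    slopes_per_min: tuple[float, ...]
    n_points_used: tuple[int, ...]
    mean_min: float
    ci95_low_min: float | None
    ci95_high_min: float | None
    ci_undefined: bool


@dataclass(frozen=True)
class RegressionResult:
    """OLS trend test of one flux ratio against one covariate."""

    ratio_name: str
    covariate_name: str
    slope: float
    intercept: float
    p_value: float
    p_adjusted: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")
        if self.p_adjusted < self.p_value - 1e-15 or self.p_adjusted > 1.0:
            raise ValidationError(
                f"p_adjusted {self.p_adjusted} inconsistent with p {self.p_value}"
            )


_RESULT_TYPES: dict[str, type] = {
    cls.__name__: cls
    for cls in (
        SizeFactors,
        QCReport,
        ClusterSignificanceResult,
        DoublingTimeEstimate,
        RegressionResult,
    )
}


def _encode(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {"type": type(obj).__name__}
        for f in dataclasses.fields(obj):
            d[f.name] = _encode(getattr(obj, f.name))
        return d
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def _decode(obj: Any) -> Any:
    if isinstance(obj, dict) and "type" in obj and obj["type"] in _RESULT_TYPES:
        cls = _RESULT_TYPES[obj["type"]]
        kwargs = {}
        for f in dataclasses.fields(cls):
            v = _decode(obj.get(f.name))
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def write_results(results: Any, path: str | Path, **params: Any) -> None:
    """Serialize one result object (or a list of them) to JSON.

    ``params`` (e.g. seed, n_perm) are echoed verbatim under ``"params"``.
    Round-trips losslessly through :func:`read_results`.
    """
    payload = {
        "schema_version": SCHEMA_VERSION,
        "params": _encode(dict(params)),
        "results": _encode(results),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_results(path: str | Path) -> Any:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported schema_version {payload.get('schema_version')!r}"
        )
    return _decode(payload["results"])
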