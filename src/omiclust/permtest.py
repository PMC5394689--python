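"""Permutation z-score test for clustering of samples by a labeled variable.

The statistic is the mean cophenetic distance over all unordered
same-label sample pairs.  The null is generated by uniformly reshuffling
the whole label vector across samples (the label multiset is preserved),
recomputing the statistic each time, and the observed statistic is
converted to a z-score with the null's sample mean and n-1 standard
deviation.  Negative z means tighter-than-random clustering; |z| > 1.96
is flagged as significant.

Two variants of the per-variable "overall" statistic exist: the default
pools the same-label pairs of every level into one pair set
(pair-weighted); ``method="level_mean"`` averages the per-level means
instead.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from omiclust.clustering import CopheneticMatrix
from omiclust.errors import ValidationError
from omiclust.io_model import ClusterSignificanceResult, SampleTable

OVERALL = "overall"
Z_THRESHOLD = 1.96
MIN_PERMUTATIONS = 100

DEFAULT_VARIABLES = ("growth_phase", "carbon_source", "na_level", "mg_level", "batch")


@dataclass(frozen=True)
class LabelVector:
    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    variable_name: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(self.sample_ids) != len(self.labels):
            raise ValidationError("sample_ids and labels differ in length")

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))


@dataclass(frozen=True)
class VariableBinning:
    """Thresholds mapping numeric ion concentrations to categorical levels.

    Defaults: Na is "base" below ``na_high_mM`` and "high" at or above it;
    Mg is "low" below, "base" at, and "high" above ``mg_base_mM`` (with a
    relative tolerance for float equality).  ``collapse_phase`` merges
    stationary and late_stationary into one level.
    """

    na_high_mM: float = 100.0
    mg_base_mM: float = 0.8
    mg_rel_tol: float = 1e-6
    collapse_phase: bool = False

    def na_level(self, na_mM: float) -> str:
        return "high" if na_mM >= self.na_high_mM else "base"

    def mg_level(self, mg_mM: float) -> str:
        if abs(mg_mM - self.mg_base_mM) <= self.mg_rel_tol * self.mg_base_mM:
            return "base"
        return "low" if mg_mM < self.mg_base_mM else "high"


def derive_labels(
    meta: SampleTable, variable: str, binning: VariableBinning | None = None
) -> LabelVector:
    """Build the label vector for one variable from sample metadata.

    ``na_level`` and ``mg_level`` are derived by binning the numeric
    concentrations; any other variable must be a metadata column.
    """
    binning = binning or VariableBinning()
    df = meta.data
    if variable == "na_level":
        labels = [binning.na_level(v) for v in df["na_mM"]]
    elif variable == "mg_level":
        labels = [binning.mg_level(v) for v in df["mg_mM"]]
    elif variable == "growth_phase" and binning.collapse_phase:
        labels = [
            "exponential" if p == "exponential" else "stationary"
            for p in df["growth_phase"]
        ]
    elif variable in df.columns:
        labels = [str(v) for v in df[variable]]
    else:
        raise ValidationError(f"variable {variable!r} absent from metadata")
    return LabelVector(meta.sample_ids, tuple(labels), variable)


def _codes(c: CopheneticMatrix, l: LabelVector) -> np.ndarray:
    if c.sample_ids != l.sample_ids:
        raise ValidationError("cophenetic matrix and labels have different samples")
    levels = l.levels
    index = {lv: k for k, lv in enumerate(levels)}
    return np.array([index[x] for x in l.labels], dtype=np.intp)


def mean_within_label_distance(
    c: CopheneticMatrix, l: LabelVector, level: str = OVERALL
) -> tuple[float, int]:
    """Mean cophenetic distance over unordered same-label pairs.

    For a specific level only pairs inside that level count; for
    ``"overall"`` the same-label pairs of every level are pooled
    (pair-weighted).
    """
    codes = _codes(c, l)
    levels = l.levels
    if level == OVERALL:
        total = 0.0
        n_pairs = 0
        for k in range(len(levels)):
            idx = np.flatnonzero(codes == k)
            m = len(idx)
            if m < 2:
                continue
            total += c.c[np.ix_(idx, idx)].sum() / 2.0
            n_pairs += m * (m - 1) // 2
        if n_pairs == 0:
            raise ValidationError("no level has 2 or more samples; no pairs to average")
        return total / n_pairs, n_pairs
    if level not in levels:
        raise ValidationError(f"level {level!r} not present for {l.variable_name!r}")
    idx = np.flatnonzero(codes == levels.index(level))
    if len(idx) < 2:
        raise ValidationError(
            f"level {level!r} has {len(idx)} sample(s); at least 2 required"
        )
    n_pairs = len(idx) * (len(idx) - 1) // 2
    return float(c.c[np.ix_(idx, idx)].sum() / 2.0 / n_pairs), n_pairs


def _null_statistics(
    c: np.ndarray, codes: np.ndarray, n_levels: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-level pair sums under random label permutations, fully vectorized.

    Returns (pair_sums[n_perm, n_levels], pair_counts[n_levels],
    overall[n_perm]); levels with < 2 members contribute zero pairs.
    """
    n = len(codes)
    perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    permuted = codes[perms]  # (n_perm, n)
    pair_sums = np.empty((n_perm, n_levels), dtype=float)
    pair_counts = np.empty(n_levels, dtype=np.int64)
    for k in range(n_levels):
        mask = (permuted == k).astype(float)
        m = int((codes == k).sum())
        pair_counts[k] = m * (m - 1) // 2
        # sum over i<j in the level: quadratic form / 2 (diagonal is zero)
        pair_sums[:, k] = np.einsum("pi,ij,pj->p", mask, c, mask) / 2.0
    total_pairs = pair_counts.sum()
    overall = pair_sums.sum(axis=1) / total_pairs if total_pairs else np.zeros(n_perm)
    return pair_sums, pair_counts, overall


def permutation_z(
    c: CopheneticMatrix,
    l: LabelVector,
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "pooled",
) -> list[ClusterSignificanceResult]:
    """Permutation z-scores for one variable: an overall result plus one per level.

    ``method="pooled"`` (default) pools same-label pairs across levels for
    the overall statistic; ``method="level_mean"`` averages per-level means.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValidationError(f"n_perm must be >= {MIN_PERMUTATIONS}, got {n_perm}")
    if seed is None:
        raise ValidationError("a seed is required for the permutation test")
    if method not in ("pooled", "level_mean"):
        raise ValidationError(f"unknown method {method!r}")
    codes = _codes(c, l)
    levels = l.levels
    n = len(codes)
    seed = int(seed)

    def result(level, obs, null_mean, null_sd, n_pairs, n_samp):
        sd = float(null_sd)
        undefined = not np.isfinite(sd) or sd == 0.0
        z = None if undefined else float((obs - null_mean) / sd)
        return ClusterSignificanceResult(
            variable_name=l.variable_name,
            level=level,
            observed_mean=float(obs),
            null_mean=float(null_mean),
            null_sd=sd,
            z=z,
            undefined=undefined,
            n_pairs=int(n_pairs),
            n_samples=int(n_samp),
            n_perm=n_perm,
            seed=seed,
        )

    if len(levels) == 1:
        # statistic is invariant under any permutation
        obs, n_pairs = mean_within_label_distance(c, l, OVERALL)
        return [result(OVERALL, obs, obs, 0.0, n_pairs, n)]

    rng = np.random.default_rng(seed)
    pair_sums, pair_counts, overall_null = _null_statistics(
        c.c, codes, len(levels), n_perm, rng
    )
    if method == "level_mean":
        usable = pair_counts > 0
        overall_null = (pair_sums[:, usable] / pair_counts[usable]).mean(axis=1)

    results = []
    if method == "pooled":
        obs_overall, n_pairs_overall = mean_within_label_distance(c, l, OVERALL)
    else:
        per_level_means = [
            mean_within_label_distance(c, l, lv)[0]
            for lv, cnt in zip(levels, pair_counts)
            if cnt > 0
        ]
        obs_overall = float(np.mean(per_level_means))
        n_pairs_overall = int(pair_counts.sum())
    results.append(
        result(
            OVERALL,
            obs_overall,
            overall_null.mean(),
            overall_null.std(ddof=1),
            n_pairs_overall,
            n,
        )
    )
    for k, lv in enumerate(levels):
        n_samp = int((codes == k).sum())
        if pair_counts[k] == 0:
            results.append(result(lv, np.nan, np.nan, 0.0, 0, n_samp))
            continue
        null_k = pair_sums[:, k] / pair_counts[k]
        obs_k, n_pairs_k = mean_within_label_distance(c, l, lv)
        results.append(
            result(lv, obs_k, null_k.mean(), null_k.std(ddof=1), n_pairs_k, n_samp)
        )
    return results


def _variable_seed(base_seed: int, variable: str) -> int:
    """Stable per-variable child seed, independent of variable order."""
    return int(
        np.random.SeedSequence(
            entropy=int(base_seed), spawn_key=(zlib.crc32(variable.encode()),)
        ).generate_state(1)[0]
    )


def run_all_variables(
    c: CopheneticMatrix,
    meta: SampleTable,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    binning: VariableBinning | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "pooled",
) -> list[ClusterSignificanceResult]:
    """Permutation z-scores for several variables against one dendrogram.

    Metadata rows are aligned to the cophenetic matrix's sample order, so
    input row order does not affect results.  Each variable gets its own
    deterministic child seed derived from ``seed`` and the variable name.
    """
    if seed is None:
        raise ValidationError("a seed is required for the permutation test")
    meta = meta.aligned_to(c.sample_ids)
    results: list[ClusterSignificanceResult] = []
    for var in variables:
        labels = derive_labels(meta, var, binning)
        results.extend(
            permutation_z(c, labels, n_perm=n_perm,
                          seed=_variable_seed(seed, var), method=method)
        )
    return results


def results_table(results: Sequence[ClusterSignificanceResult]) -> pd.DataFrame:
    """Tabular view mirroring a (variable, level, z, n) summary table."""
    rows = []
    for r in results:
        rows.append(
            {
                "variable": r.variable_name,
                "level": r.level,
                "z": r.z,
                "significant": (r.z is not None and abs(r.z) > Z_THRESHOLD),
                "observed_mean": r.observed_mean,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "n_samples": r.n_samples,
                "n_pairs": r.n_pairs,
            }
        )
    return pd.DataFrame(rows)
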