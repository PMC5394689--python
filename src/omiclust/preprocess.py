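"""Replicate QC, size-factor normalization, and log transformation.

Size factors follow the median-of-ratios construction with a +1
pseudocount applied *only* while computing the factors; the raw counts
(without pseudocounts) are then divided by the factors.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from omiclust.errors import ValidationError
from omiclust.io_model import CountMatrix, QCReport, SizeFactors

MIN_CODETECTED_GENES = 50


def check_replicate_consistency(
    a: np.ndarray,
    b: np.ndarray,
    flag_threshold: float = 0.5,
    sample_a: str = "a",
    sample_b: str = "b",
) -> QCReport:
    """Summarize per-gene log2 count differences between two replicates.

    Only genes detected (count > 0) in both samples contribute.  The pair
    is flagged when the median log2 difference exceeds ``flag_threshold``
    in absolute value; skewness is reported so callers can apply their own
    shape criteria.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("replicate columns must be 1-D of equal length")
    if flag_threshold <= 0:
        raise ValidationError("flag_threshold must be > 0")
    mask = (a > 0) & (b > 0)
    n = int(mask.sum())
    if n < MIN_CODETECTED_GENES:
        raise ValidationError(
            f"only {n} genes detected in both {sample_a!r} and {sample_b!r}; "
            f"at least {MIN_CODETECTED_GENES} required for an informative histogram"
        )
    diffs = np.log2(a[mask]) - np.log2(b[mask])
    # near-constant differences (e.g. exact rescalings) carry no shape info
    skewness = float(stats.skew(diffs)) if np.ptp(diffs) > 1e-9 else 0.0
    median = float(np.median(diffs))
    q75, q25 = np.percentile(diffs, [75, 25])
    flagged = abs(median) > flag_threshold
    note = "median log2 difference exceeds threshold" if flagged else ""
    return QCReport(
        sample_a=sample_a,
        sample_b=sample_b,
        n_genes_used=n,
        median_log2_diff=median,
        iqr_log2_diff=float(q75 - q25),
        skewness=skewness,
        flag_threshold=float(flag_threshold),
        flagged=bool(flagged),
        note=note,
    )


def compute_size_factors(m: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors on the pseudocounted (+1) matrix.

    For each gene the reference is the geometric mean of ``count + 1``
    across samples; a sample's factor is the median over genes of
    ``(count + 1) / reference``.
    """
    if m.n_genes == 0 or m.n_samples == 0:
        raise ValidationError("count matrix is empty")
    pseudo = m.counts.astype(float) + 1.0
    ref = np.exp(np.log(pseudo).mean(axis=1))  # geometric mean per gene
    # median taken over the ratios themselves (matters for even gene counts,
    # where the two middle values are averaged arithmetically)
    factors = np.median(pseudo / ref[:, None], axis=0)
    for s, f in zip(m.sample_ids, factors):
        if not np.isfinite(f) or f <= 0:
            raise ValidationError(f"degenerate size factor for sample {s!r}: {f}")
    return SizeFactors(sample_ids=m.sample_ids, factors=tuple(factors))


def normalize_counts(m: CountMatrix, f: SizeFactors) -> np.ndarray:
    """Divide the *raw* counts (no pseudocount) by the per-sample factors."""
    lookup = f.as_dict()
    missing = [s for s in m.sample_ids if s not in lookup]
    if missing:
        raise ValidationError(f"size factors missing for samples: {missing}")
    factors = np.array([lookup[s] for s in m.sample_ids], dtype=float)
    return m.counts.astype(float) / factors[None, :]


def log_transform(
    matrix: np.ndarray, pseudocount: float = 1.0, base: float = 2.0
) -> np.ndarray:
    """Elementwise ``log_base(value + pseudocount)``; monotone in the input."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    if base <= 1:
        raise ValidationError("log base must be > 1")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size and matrix.min() < 0:
        idx = np.unravel_index(int(np.argmin(matrix)), matrix.shape)
        raise ValidationError(f"negative input cell at {idx}: {matrix[idx]}")
    return np.log(matrix + pseudocount) / np.log(base)


def qc_replicate_pairs(
    m: CountMatrix,
    condition_of: dict[str, str],
    flag_threshold: float = 0.5,
) -> list[QCReport]:
    """Run :func:`check_replicate_consistency` for every same-condition pair."""
    by_condition: dict[str, list[str]] = {}
    for s in m.sample_ids:
        if s not in condition_of:
            raise ValidationError(f"no condition assignment for sample {s!r}")
        by_condition.setdefault(condition_of[s], []).append(s)
    col = {s: i for i, s in enumerate(m.sample_ids)}
    reports = []
    for _, samples in sorted(by_condition.items()):
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                a, b = samples[i], samples[j]
                reports.append(
                    check_replicate_consistency(
                        m.counts[:, col[a]],
                        m.counts[:, col[b]],
                        flag_threshold=flag_threshold,
                        sample_a=a,
                        sample_b=b,
                    )
                )
    return reports
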