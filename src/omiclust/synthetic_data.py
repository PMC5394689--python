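"""Seeded generators for count matrices, growth curves, and flux tables.

Counts are negative-binomial with per-gene baseline log2 means and
additive log2-scale shifts planted for a configurable subset of genes per
experimental variable.  Two presets mimic the contrast seen between the
two omics layers: an "mrna-like" regime where the growth-phase effect
dominates, and a "protein-like" regime dominated by batch and
carbon-source effects.  All generators are bit-reproducible under a fixed
seed (PCG64 via :func:`numpy.random.default_rng`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from omiclust.errors import ValidationError
from omiclust.io_model import CountMatrix, FluxRatioTable, GrowthCurve, SampleTable
from omiclust.io_model import DEFAULT_FLUX_RATIO_NAMES


@dataclass(frozen=True)
class EffectSpec:
    """Planted effect of one variable: log2 shift applied to a gene fraction."""

    size_log2: float
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError(f"effect fraction {self.fraction} outside [0, 1]")
        if self.size_log2 < 0:
            raise ValidationError("effect size must be nonnegative")


@dataclass(frozen=True)
class SimulationDesign:
    n_genes: int
    samples: pd.DataFrame  # metadata-like table, one row per sample
    effects: Mapping[str, EffectSpec]
    dispersion: float = 0.1
    baseline_mean_log2: float = 6.0
    baseline_sd_log2: float = 2.0
    omics_kind: str = "mrna"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        for var in self.effects:
            if var not in self.samples.columns:
                raise ValidationError(f"effect variable {var!r} not a sample column")


@dataclass(frozen=True)
class SimulatedDataset:
    counts: CountMatrix
    metadata: SampleTable
    ground_truth: dict  # variable -> {gene_id -> {level -> log2 shift}}


def default_sample_design() -> pd.DataFrame:
    """48-sample factorial design: 2 phases x 2 carbons x 3 batches x 4 replicates.

    The four replicates within each (phase, carbon, batch) cell carry the
    four ion settings base/high-Na/low-Mg/high-Mg so that na_mM and mg_mM
    are balanced across every other variable.
    """
    ion_settings = [(5.0, 0.8), (100.0, 0.8), (5.0, 0.02), (5.0, 200.0)]
    rows = []
    for phase in ("exponential", "stationary"):
        for carbon in ("glucose", "glycerol"):
            for batch in ("b1", "b2", "b3"):
                for rep, (na, mg) in enumerate(ion_settings, start=1):
                    rows.append(
                        {
                            "growth_phase": phase,
                            "carbon_source": carbon,
                            "na_mM": na,
                            "mg_mM": mg,
                            "batch": batch,
                            "replicate": f"r{rep}",
                        }
                    )
    return pd.DataFrame(rows)


def paper_scale_sample_design() -> pd.DataFrame:
    """Larger design (~152 samples) spanning all three growth phases and
    four carbon sources, for heavier-duty runs."""
    ion_settings = [(5.0, 0.8), (100.0, 0.8), (300.0, 0.8), (5.0, 0.02), (5.0, 200.0)]
    rows = []
    for phase in ("exponential", "stationary", "late_stationary"):
        for carbon in ("glucose", "glycerol", "lactate", "gluconate"):
            for batch in ("b1", "b2"):
                for rep, (na, mg) in enumerate(ion_settings, start=1):
                    rows.append(
                        {
                            "growth_phase": phase,
                            "carbon_source": carbon,
                            "na_mM": na,
                            "mg_mM": mg,
                            "batch": batch,
                            "replicate": f"r{rep}",
                        }
                    )
    # 3 * 4 * 2 * 5 = 120; add extra glucose-base replicates to reach 152
    for k in range(32):
        rows.append(
            {
                "growth_phase": ("exponential", "stationary")[k % 2],
                "carbon_source": "glucose",
                "na_mM": 5.0,
                "mg_mM": 0.8,
                "batch": ("b1", "b2")[(k // 2) % 2],
                "replicate": f"x{k + 1}",
            }
        )
    return pd.DataFrame(rows)


#: Planted effect sizes of the presets (log2 shift, affected gene fraction).
PRESET_EFFECTS: dict[str, dict[str, EffectSpec]] = {
    "null": {},
    "mrna-like": {
        "growth_phase": EffectSpec(2.0, 0.30),
        "carbon_source": EffectSpec(0.4, 0.10),
        "batch": EffectSpec(0.2, 0.10),
    },
    "protein-like": {
        "batch": EffectSpec(1.5, 0.30),
        "carbon_source": EffectSpec(1.6, 0.25),
        "growth_phase": EffectSpec(0.1, 0.05),
    },
}


def preset_design(
    preset: str,
    n_genes: int = 1000,
    seed: int = 0,
    paper_scale: bool = False,
) -> SimulationDesign:
    if preset not in PRESET_EFFECTS:
        raise ValidationError(
            f"unknown preset {preset!r}; available: {sorted(PRESET_EFFECTS)}"
        )
    samples = paper_scale_sample_design() if paper_scale else default_sample_design()
    if paper_scale:
        n_genes = max(n_genes, 4196)
    return SimulationDesign(
        n_genes=n_genes,
        samples=samples,
        effects=PRESET_EFFECTS[preset],
        omics_kind="protein" if preset == "protein-like" else "mrna",
        seed=seed,
    )


def simulate_counts(design: SimulationDesign) -> SimulatedDataset:
    """Draw a negative-binomial count matrix with the planted shifts.

    ``count_gs ~ NB(mean = 2 ** (baseline_g + sum of shifts), dispersion)``
    where each affected gene receives a random-sign shift of the declared
    size for every non-reference level of the variable.
    """
    rng = np.random.default_rng(design.seed)
    n_genes = design.n_genes
    samples = design.samples.reset_index(drop=True)
    n_samples = len(samples)
    gene_ids = tuple(f"g{(i + 1):05d}" for i in range(n_genes))
    sample_ids = tuple(f"s{(j + 1):03d}" for j in range(n_samples))

    baseline = rng.normal(design.baseline_mean_log2, design.baseline_sd_log2, n_genes)
    log2_mean = np.tile(baseline[:, None], (1, n_samples))

    ground_truth: dict[str, dict[str, dict[str, float]]] = {}
    for var in sorted(design.effects):
        spec = design.effects[var]
        levels = sorted(set(str(v) for v in samples[var]))
        col = np.array([str(v) for v in samples[var]])
        n_affected = int(round(spec.fraction * n_genes))
        affected = rng.choice(n_genes, size=n_affected, replace=False)
        shifts = np.zeros((n_genes, len(levels)))
        # reference level (first) stays 0; others get +/- size per gene
        signs = rng.choice([-1.0, 1.0], size=(n_affected, len(levels) - 1))
        shifts[affected, 1:] = spec.size_log2 * signs
        level_idx = np.array([levels.index(v) for v in col])
        log2_mean += shifts[:, level_idx]
        ground_truth[var] = {
            gene_ids[g]: {lv: float(shifts[g, k]) for k, lv in enumerate(levels)}
            for g in affected
        }

    mu = np.exp2(log2_mean)
    size = 1.0 / design.dispersion  # NB shape; var = mu + dispersion * mu^2
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p).astype(np.int64)

    matrix = CountMatrix(gene_ids, sample_ids, counts, design.omics_kind)
    meta = samples.copy()
    meta.insert(0, "sample_id", list(sample_ids))
    meta.insert(1, "omics_kind", design.omics_kind)
    return SimulatedDataset(matrix, SampleTable(meta), ground_truth)


def simulate_growth_curve(
    true_doubling_min: float,
    od0: float = 0.01,
    plateau: float = 1.0,
    noise_sigma: float = 0.0,
    dt_min: float = 10.0,
    seed: int = 0,
    replicate_id: str = "r1",
    condition_id: str = "c1",
) -> GrowthCurve:
    """Exponential-then-plateau OD curve with multiplicative log-normal noise."""
    if true_doubling_min <= 0:
        raise ValidationError("true_doubling_min must be > 0")
    if not 0 < od0 < plateau:
        raise ValidationError("require 0 < od0 < plateau")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    t_plateau = true_doubling_min * np.log2(plateau / od0)
    n_points = int(np.ceil(t_plateau / dt_min)) + 4  # a few stationary readings
    t = np.arange(n_points, dtype=float) * dt_min
    od = np.minimum(od0 * np.exp2(t / true_doubling_min), plateau)
    if noise_sigma > 0:
        od = od * np.exp(rng.normal(0.0, noise_sigma, size=n_points))
    return GrowthCurve(replicate_id, condition_id, t, od)


def simulate_flux_table(
    n_conditions: int = 8,
    slope_per_ratio: Sequence[float] | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    covariate_range: tuple[float, float] = (50.0, 100.0),
    n_replicates: int = 3,
    ratio_names: Sequence[str] = DEFAULT_FLUX_RATIO_NAMES,
) -> FluxRatioTable:
    """Flux-ratio table linear in a doubling-time-like covariate.

    ``value = intercept_r + slope_r * (covariate - midpoint) + noise``,
    clipped to [0, 1]; slopes are per minute of doubling time.
    """
    if slope_per_ratio is None:
        slope_per_ratio = [0.0] * len(ratio_names)
    if len(slope_per_ratio) != len(ratio_names):
        raise ValidationError("slope_per_ratio length must match ratio_names")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = covariate_range
    covariates = np.linspace(lo, hi, n_conditions)
    mid = 0.5 * (lo + hi)
    intercepts = rng.uniform(0.35, 0.65, size=len(ratio_names))
    rows = []
    for ci, cov in enumerate(covariates):
        cond = f"cond{ci + 1:02d}"
        for ri, (name, slope) in enumerate(zip(ratio_names, slope_per_ratio)):
            mean = intercepts[ri] + slope * (cov - mid)
            for rep in range(1, n_replicates + 1):
                value = mean + rng.normal(0.0, noise_sd) if noise_sd > 0 else mean
                rows.append(
                    {
                        "sample_id": f"{cond}_r{rep}",
                        "condition_id": cond,
                        "replicate": f"r{rep}",
                        "na_mM": 5.0,
                        "mg_mM": 0.8,
                        "doubling_time_min": float(cov),
                        "ratio_name": name,
                        "value": float(np.clip(value, 0.0, 1.0)),
                    }
                )
    return FluxRatioTable(pd.DataFrame(rows), tuple(ratio_names))
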