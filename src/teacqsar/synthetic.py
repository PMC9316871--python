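"""Synthetic descriptor/activity datasets with QSAR-like structure.

Real descriptor matrices for this problem come from commercial descriptor
software and are not redistributable, so the whole modeling pipeline is
exercised on generated data instead: latent standard-normal descriptors,
optional correlated blocks (shared-factor mixing, x = sqrt(rho) f +
sqrt(1-rho) e, giving exact pairwise correlation rho in expectation),
constant columns that the pre-filter must drop, and an activity built as a
linear signal over min-max-normalized informative columns plus Gaussian
noise, optionally clipped at zero as a non-negative assay readout demands.

``make_paper_like_dataset`` reproduces the study conditions: 72 compounds,
4 informative descriptors carrying the published four-variable TEAC
coefficients among 200 correlated noise descriptors, residual SD 0.0428 mM
and clipping at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DescriptorTable

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_descriptors",
    "generate_activity",
    "make_paper_like_dataset",
    "MODEL4_COEFFICIENTS",
    "MODEL4_INTERCEPT",
    "MODEL4_NOISE_SD",
]

#: The published four-variable TEAC equation, reused as the default truth.
MODEL4_COEFFICIENTS = {
    "Mor16e": -0.0851,
    "RDF145p": -0.1511,
    "C-018": 0.1489,
    "CATS2D_06_AL": 0.1991,
}
MODEL4_INTERCEPT = 0.0396
MODEL4_NOISE_SD = 0.0428


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset; same spec + seed => same data."""

    n_compounds: int
    n_descriptors: int
    informative_names: list[str] = field(default_factory=list)
    true_coefficients: dict[str, float] = field(default_factory=dict)
    true_intercept: float = 0.0
    noise_sd: float = 0.0
    block_correlation: float = 0.0
    block_size: int = 5
    n_constant_columns: int = 0
    clip_at_zero: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_descriptors < 1:
            raise ValueError("non-positive dimensions")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_constant_columns < 0 or self.n_constant_columns > self.n_descriptors:
            raise ValueError("invalid n_constant_columns")
        if len(self.informative_names) > self.n_descriptors - self.n_constant_columns:
            raise ValueError("more informative names than variable columns")
        unknown = set(self.true_coefficients) - set(self.informative_names)
        if unknown:
            raise ValueError(f"coefficients for non-informative names: {unknown}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticDataset:
    """Generated table plus the ground truth that produced its activity."""

    descriptor_table: DescriptorTable
    informative_names: list[str]
    true_coefficients: dict[str, float]
    true_intercept: float
    noise_sd: float


def generate_descriptors(spec: SyntheticSpec) -> DescriptorTable:
    """Draw the descriptor matrix of a spec.

    Informative columns are independent standard normals; the remaining
    non-constant columns are grouped into consecutive blocks of
    ``block_size`` sharing a latent factor so that every within-block pair
    has correlation ``block_correlation``; constant columns sit at the end.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    n_informative = len(spec.informative_names)
    n_noise = spec.n_descriptors - spec.n_constant_columns - n_informative
    if n_noise < 0:
        raise ValueError("descriptor budget smaller than informative + constant")

    columns: dict[str, np.ndarray] = {}
    for name in spec.informative_names:
        columns[name] = rng.standard_normal(n)

    rho = spec.block_correlation
    made = 0
    while made < n_noise:
        width = min(spec.block_size, n_noise - made)
        factor = rng.standard_normal(n)
        for _ in range(width):
            eps = rng.standard_normal(n)
            columns[f"D{made + 1:04d}"] = (np.sqrt(rho) * factor
                                           + np.sqrt(1.0 - rho) * eps)
            made += 1
    for j in range(spec.n_constant_columns):
        columns[f"const{j + 1}"] = np.full(n, 1.0)

    ids = [f"cpd{i + 1:03d}" for i in range(n)]
    return DescriptorTable(pd.DataFrame(columns, index=ids))


def generate_activity(table: DescriptorTable, spec: SyntheticSpec) -> SyntheticDataset:
    """Attach an activity column: linear signal over min-max-normalized
    informative columns plus N(0, noise_sd) noise, clipped at zero when the
    spec says so (clipped points are kept, not resampled)."""
    missing = [n for n in spec.informative_names if n not in table.data.columns]
    if missing:
        raise KeyError(f"informative columns absent from table: {missing}")
    rng = np.random.default_rng(spec.seed + 1)  # independent of descriptor draw
    signal = np.full(table.n_compounds, float(spec.true_intercept))
    for name, coef in spec.true_coefficients.items():
        col = table.data[name].to_numpy(dtype=float)
        span = col.max() - col.min()
        normalized = (col - col.min()) / span if span > 0 else np.zeros_like(col)
        signal = signal + coef * normalized
    activity = signal + rng.normal(0.0, spec.noise_sd, size=table.n_compounds)
    if spec.clip_at_zero:
        activity = np.clip(activity, 0.0, None)
    out = DescriptorTable(table.data.copy(),
                          pd.Series(activity, index=table.data.index))
    return SyntheticDataset(
        descriptor_table=out,
        informative_names=list(spec.informative_names),
        true_coefficients=dict(spec.true_coefficients),
        true_intercept=spec.true_intercept,
        noise_sd=spec.noise_sd,
    )


def paper_like_spec(seed: int = 0, n_compounds: int = 72,
                    clip_at_zero: bool = True) -> SyntheticSpec:
    """The study-scale recipe: 4 informative + 200 correlated noise + 3
    constant descriptors, published coefficients, residual SD 0.0428 mM."""
    return SyntheticSpec(
        n_compounds=n_compounds,
        n_descriptors=207,
        informative_names=list(MODEL4_COEFFICIENTS),
        true_coefficients=dict(MODEL4_COEFFICIENTS),
        true_intercept=MODEL4_INTERCEPT,
        noise_sd=MODEL4_NOISE_SD,
        block_correlation=0.8,
        block_size=5,
        n_constant_columns=3,
        clip_at_zero=clip_at_zero,
        seed=seed,
    )


def make_paper_like_dataset(seed: int = 0) -> SyntheticDataset:
    """Generate one study-scale dataset (72 compounds, 207 descriptors)."""
    spec = paper_like_spec(seed=seed)
    return generate_activity(generate_descriptors(spec), spec)
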