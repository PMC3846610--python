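"""Synthetic expression matrices with planted pattern genes and known truth.

The generator emulates the data structure the classifier consumes: a
nonnegative genes x samples matrix in which each gene belongs to one of
five planted classes — specific (one high sample), selective (k high
samples), housekeeping (flat background), repressed (background with k
silent samples) and unpatterned (pure noise around background).  Noise is
multiplicative lognormal, the natural first model for nonnegative,
right-skewed intensity data; probe effects, batch structure and
array-specific artifacts are deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "generate", "write_synthetic"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic matrix.

    ``fold_enrichment`` is the ratio of the high level of specific and
    selective genes to the background level; ``noise_cv`` the coefficient
    of variation of the multiplicative lognormal noise.  ``repressed_floor``
    optionally replaces the exact zeros of repressed samples with a small
    positive level (times noise) so the repression ratio is exercised away
    from its trivial 0.
    """

    n_samples: int = 12
    n_specific: int = 100
    n_selective: int = 100
    n_housekeeping: int = 100
    n_repressed: int = 100
    n_unpatterned: int = 0
    base_expression: float = 100.0
    fold_enrichment: float = 20.0
    noise_cv: float = 0.05
    k_selective: int = 3
    k_repressed: int = 2
    repressed_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 5:
            raise ValueError("need at least 5 samples for meaningful pattern statistics")
        if self.fold_enrichment <= 1:
            raise ValueError("fold_enrichment must exceed 1")
        if not 1 <= self.k_selective < self.n_samples:
            raise ValueError("k_selective must lie in [1, n_samples)")
        if not 1 <= self.k_repressed < self.n_samples:
            raise ValueError("k_repressed must lie in [1, n_samples)")
        if self.base_expression <= 0:
            raise ValueError("base_expression must be positive")
        if self.noise_cv < 0 or self.repressed_floor < 0:
            raise ValueError("noise_cv and repressed_floor must be nonnegative")
        for name in ("n_specific", "n_selective", "n_housekeeping", "n_repressed", "n_unpatterned"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (matrix, truth) for the given conditions.

    ``matrix`` is a genes x samples DataFrame; ``truth`` has one row per
    gene with its planted class and the planted sample labels
    (';'-joined; empty for housekeeping and unpatterned genes).
    Reproducible for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{j + 1:02d}" for j in range(n)]
    base, high = config.base_expression, config.base_expression * config.fold_enrichment

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    truth_rows: list[tuple[str, str, str]] = []

    def add(gene_id: str, cls: str, values: np.ndarray, planted: list[int]) -> None:
        gene_ids.append(gene_id)
        rows.append(values)
        truth_rows.append((gene_id, cls, ";".join(samples[j] for j in planted)))

    for g in range(config.n_specific):
        j = int(rng.integers(n))
        v = np.full(n, base)
        v[j] = high
        add(f"SPEC{g + 1:04d}", "specific", v * _noise(rng, config.noise_cv, n), [j])

    for g in range(config.n_selective):
        idx = sorted(rng.choice(n, size=config.k_selective, replace=False).tolist())
        v = np.full(n, base)
        v[idx] = high
        add(f"SEL{g + 1:04d}", "selective", v * _noise(rng, config.noise_cv, n), idx)

    for g in range(config.n_housekeeping):
        v = np.full(n, base)
        add(f"HK{g + 1:04d}", "housekeeping", v * _noise(rng, config.noise_cv, n), [])

    for g in range(config.n_repressed):
        idx = sorted(rng.choice(n, size=config.k_repressed, replace=False).tolist())
        v = np.full(n, base)
        v[idx] = config.repressed_floor
        add(f"REP{g + 1:04d}", "repressed", v * _noise(rng, config.noise_cv, n), idx)

    for g in range(config.n_unpatterned):
        v = base * rng.lognormal(mean=0.0, sigma=1.0, size=n)
        add(f"BG{g + 1:04d}", "unpatterned", v, [])

    matrix = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "pattern_class", "samples"]).set_index(
        "gene_id"
    )
    return matrix, truth


def write_synthetic(config: SyntheticConfig, matrix_path, truth_path) -> None:
    """Generate and write the matrix and truth table as TSV."""
    matrix, truth = generate(config)
    matrix.to_csv(Path(matrix_path), sep="\t", float_format="%.6g")
    truth.to_csv(Path(truth_path), sep="\t")
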