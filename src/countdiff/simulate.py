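"""Synthetic Poisson count matrices for calibration, coverage and power studies.

The generator draws one true expression level λ_g per gene (log-uniform
over [λ_min, λ_max] by default, spanning low to very high expression) and
produces lane counts x_{gj} ~ Poisson(λ_g · size_factor_j), with the
condition-2 mean multiplied by a known fold for a spiked fraction of DE
genes. Technical replicates of one condition therefore share a gene's
mean up to the lane-specific library-size factor — the ideal
no-overdispersion regime the count tests assume.

Randomness is reproducible: each gene has its own substream derived from
the global seed via spawn keys, so enlarging ``n_genes`` leaves the counts
of existing genes unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .count_io import CountMatrix
from .errors import DesignError

__all__ = [
    "SimulationDesign",
    "SimulatedTruth",
    "simulate_counts",
    "type1_experiment",
]


@dataclass
class SimulationDesign:
    """Parameters of one synthetic experiment.

    λ_g is log-uniform on [lambda_min, lambda_max]; set the two equal for a
    fixed mean. ``size_factors`` holds one positive multiplier per lane
    (m + n entries, condition-1 lanes first), defaulting to all ones.
    ``de_fraction`` of genes get their condition-2 mean multiplied by
    ``fold``.
    """

    n_genes: int
    m: int = 2
    n: int = 2
    lambda_min: float = 5.0
    lambda_max: float = 5000.0
    size_factors: np.ndarray | None = None
    de_fraction: float = 0.0
    fold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.m < 1 or self.n < 1:
            raise DesignError("n_genes, m, n must be positive")
        if not (0.0 < self.lambda_min <= self.lambda_max):
            raise DesignError("need 0 < lambda_min <= lambda_max")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise DesignError("de_fraction must lie in [0, 1]")
        if self.fold <= 0:
            raise DesignError("fold must be positive")
        if self.size_factors is None:
            self.size_factors = np.ones(self.m + self.n)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if self.size_factors.size != self.m + self.n or (self.size_factors <= 0).any():
            raise DesignError("size_factors needs m + n positive entries")


@dataclass
class SimulatedTruth:
    """Ground truth of a simulated matrix: per-gene mean, DE flag, applied fold."""

    lam: np.ndarray
    is_de: np.ndarray
    fold: np.ndarray

    def frame(self, gene_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": gene_ids, "lambda": self.lam, "is_de": self.is_de, "fold": self.fold}
        )


def _gene_rng(seed: int, gene: int) -> np.random.Generator:
    # per-gene substream: adding genes never reshuffles earlier ones
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(gene,)))


def simulate_counts(design: SimulationDesign) -> tuple[CountMatrix, SimulatedTruth]:
    """Draw a gene × lane Poisson count matrix plus its ground truth."""
    g, m, n = design.n_genes, design.m, design.n
    sf = design.size_factors
    counts = np.empty((g, m + n), dtype=np.int64)
    lam = np.empty(g)
    is_de = np.zeros(g, dtype=bool)
    fold = np.ones(g)
    log_lo, log_hi = np.log(design.lambda_min), np.log(design.lambda_max)
    for i in range(g):
        rng = _gene_rng(design.seed, i)
        lam[i] = float(np.exp(rng.uniform(log_lo, log_hi)))
        is_de[i] = rng.random() < design.de_fraction
        if is_de[i]:
            fold[i] = design.fold
        mean = lam[i] * sf
        mean[m:] *= fold[i]
        counts[i] = rng.poisson(mean)
    lanes = [f"c1_r{j + 1}" for j in range(m)] + [f"c2_r{j + 1}" for j in range(n)]
    conditions = {lane: ("cond1" if j < m else "cond2") for j, lane in enumerate(lanes)}
    df = pd.DataFrame(counts.astype(float), index=[f"g{i + 1}" for i in range(g)], columns=lanes)
    df.index.name = "gene_id"
    return CountMatrix(df, conditions, is_integer=True), SimulatedTruth(lam, is_de, fold)


def type1_experiment(
    design: SimulationDesign,
    levels=(0.01, 0.025, 0.05, 0.10),
    method: str = "lrt",
) -> dict[float, tuple[float, float]]:
    """Empirical per-gene rejection rates on null (no-DE) simulated data.

    Returns {level: (rejection rate, Monte-Carlo standard error)}. For the
    likelihood-ratio method the level is the chi-square test level; for the
    Bayesian method it is the per-tail α, and the rate is the non-coverage
    frequency of the acceptance interval (requires m = n).
    """
    if design.de_fraction != 0.0:
        raise DesignError("type-I experiment requires de_fraction = 0")
    if method not in ("lrt", "bayes"):
        raise ValueError(f"unknown method {method!r}")
    cm, _ = simulate_counts(design)
    g = design.n_genes
    out: dict[float, tuple[float, float]] = {}
    if method == "lrt":
        from .lrt import de_lrt

        p = de_lrt(cm).records["p_value"].to_numpy()
        for lvl in levels:
            rate = float(np.mean(p <= lvl))
            out[lvl] = (rate, float(np.sqrt(lvl * (1 - lvl) / g)))
    else:
        from .bayes import de_bayes

        x = np.rint(cm.pooled("cond1")).astype(int)
        y = np.rint(cm.pooled("cond2")).astype(int)
        for lvl in levels:
            miss = np.fromiter(
                (de_bayes(xi, yi, design.m, design.n, alpha=lvl)[0] for xi, yi in zip(x, y)),
                dtype=bool,
                count=g,
            )
            rate = float(miss.mean())
            out[lvl] = (rate, float(np.sqrt(rate * (1 - rate) / g)))
    return out
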