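"""Multi-study negative-binomial RNA-seq simulator with planted concordance.

Emulates the three-model comparison design: a *reference* study (the
analogue of spaceflight mice) and comparison studies whose true log2
effects correlate with the reference's at a chosen level rho.  Ground
truth is planted, so pipeline behaviour — which comparison model the
distance statistic ranks closer to the reference — can be checked against
what was simulated.

Effect model.  A fraction ``f_de`` of genes is differential in the
reference, with log2 effects beta_ref ~ N(0, sigma_beta^2).  For a study
with concordance rho, the same genes get

    beta_study = rho * beta_ref + sqrt(1 - rho^2) * eta,   eta ~ N(0, sigma_beta^2)

so corr(beta_study, beta_ref) = rho over the differential genes, and both
marginals share the same spread.  Non-differential genes have beta = 0
everywhere.  A useful closed form: the gap |beta_study - beta_ref| is
half-normal with mean 2 * sigma_beta * sqrt((1 - rho) / pi), which the
test suite checks by Monte Carlo.

Count model.  Counts are negative binomial with mean
mu_g * 2^(beta * x) (x = 1 for treated samples) and variance
mu + phi * mu^2 — i.e. ``phi`` is the overdispersion on the squared-mean
term, the parameterisation used by gamma-Poisson RNA-seq models.
Baseline means mu_g are log-normal.

Randomness.  One master seed; each study draws from substreams derived by
hashing (seed, study label), so adding a study to a config never perturbs
the studies already simulated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .de import CONTROL, TREATED, CountMatrix, GroupDesign

__all__ = ["SimConfig", "EffectTruth", "simulate_truth", "simulate_counts", "simulate_panel"]


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters.

    Defaults mirror the three-model study design: three two-group studies
    of 6 animals per group, 5000 genes with 10% differential, unit-SD
    log2 effects, moderate overdispersion (phi = 0.3), one fully
    concordant reference ("FL") plus a strongly (0.8) and a weakly (0.2)
    concordant comparison model.
    """

    n_genes: int = 5000
    n_per_group: int = 6
    f_de: float = 0.1
    sigma_beta: float = 1.0
    rho: Mapping[str, float] = field(
        default_factory=lambda: {"FL": 1.0, "CS": 0.8, "HU": 0.2}
    )
    reference: str = "FL"
    phi: float = 0.3
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    private_de_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0.0 < self.f_de <= 1.0):
            raise ValueError("f_de must lie in (0, 1]")
        if self.sigma_beta <= 0:
            raise ValueError("sigma_beta must be positive")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if not (0.0 <= self.private_de_frac < 1.0):
            raise ValueError("private_de_frac must lie in [0, 1)")
        if not self.rho:
            raise ValueError("rho must name at least one study")
        for lab, r in self.rho.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"rho[{lab!r}] must lie in [0, 1], got {r}")

    @property
    def studies(self) -> list[str]:
        return list(self.rho)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _substream(seed: int, *context: str) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, context strings).

    crc32 hashes the context so a study's stream depends only on its own
    label, never on the other studies present.
    """
    key = tuple(zlib.crc32(c.encode()) for c in context)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class EffectTruth:
    """Planted per-gene truth: reference effects and per-study effects.

    ``beta`` is genes × studies; ``is_de`` flags the reference-differential
    genes (beta_ref != 0); study-private differential genes, if enabled,
    are nonzero in ``beta`` but not flagged in ``is_de``.
    """

    genes: list[str]
    is_de: np.ndarray
    beta_ref: np.ndarray
    beta: pd.DataFrame = field(repr=False)

    @property
    def studies(self) -> list[str]:
        return list(self.beta.columns)

    def study_beta(self, study: str) -> np.ndarray:
        if study not in self.beta.columns:
            raise KeyError(f"unknown study {study!r}; have {self.studies}")
        return self.beta[study].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {"is_de": self.is_de.astype(int), "beta_ref": self.beta_ref},
            index=pd.Index(self.genes, name="gene_id"),
        )
        for s in self.studies:
            out[f"beta_{s}"] = self.study_beta(s)
        out.to_csv(path, sep="\t")


def simulate_truth(config: SimConfig) -> EffectTruth:
    """Draw the planted effect structure for every study in the config."""
    G = config.n_genes
    width = len(str(G))
    genes = [f"g{i:0{width}d}" for i in range(1, G + 1)]

    master = _substream(config.seed, "truth")
    n_de = round(G * config.f_de)
    de_idx = np.sort(master.choice(G, size=n_de, replace=False))
    is_de = np.zeros(G, dtype=bool)
    is_de[de_idx] = True

    beta_ref = np.zeros(G)
    beta_ref[is_de] = master.normal(0.0, config.sigma_beta, size=n_de)

    beta = {}
    for study, rho in config.rho.items():
        rng = _substream(config.seed, study, "effects")
        eta = rng.normal(0.0, config.sigma_beta, size=n_de)
        b = np.zeros(G)
        b[is_de] = rho * beta_ref[is_de] + np.sqrt(1.0 - rho**2) * eta
        if config.private_de_frac > 0:
            non_de = np.flatnonzero(~is_de)
            n_priv = round(G * config.private_de_frac)
            n_priv = min(n_priv, len(non_de))
            priv = rng.choice(non_de, size=n_priv, replace=False)
            b[priv] = rng.normal(0.0, config.sigma_beta, size=n_priv)
        beta[study] = b

    return EffectTruth(
        genes=genes,
        is_de=is_de,
        beta_ref=beta_ref,
        beta=pd.DataFrame(beta, index=pd.Index(genes, name="gene_id")),
    )


def simulate_counts(
    truth: EffectTruth, config: SimConfig, study: str
) -> tuple[CountMatrix, GroupDesign]:
    """Draw one study's NB count matrix and its two-group design.

    Counts ~ NB(mean = mu_g * 2^(beta_study * x_s), variance = mu + phi*mu^2)
    with x_s = 1 for treated samples; mu_g log-normal with the configured
    baseline parameters.  Deterministic given (seed, study).
    """
    b = truth.study_beta(study)
    G = len(truth.genes)
    n = config.n_per_group

    rng_mu = _substream(config.seed, study, "baseline")
    mu = np.exp(rng_mu.normal(config.baseline_log_mean, config.baseline_log_sd, size=G))

    rng = _substream(config.seed, study, "counts")
    r = 1.0 / config.phi  # NB size: variance = mu + mu^2 / r
    mean = np.empty((G, 2 * n))
    mean[:, :n] = mu[:, None]  # control
    mean[:, n:] = (mu * 2.0**b)[:, None]  # treated
    counts = rng.negative_binomial(r, r / (r + mean))

    samples = [f"{study}_c{i + 1}" for i in range(n)] + [
        f"{study}_t{i + 1}" for i in range(n)
    ]
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(truth.genes, name="gene_id"), columns=samples)
    )
    design = GroupDesign(
        {s: (CONTROL if i < n else TREATED) for i, s in enumerate(samples)}
    )
    return cm, design


def simulate_panel(
    config: SimConfig,
) -> tuple[dict[str, tuple[CountMatrix, GroupDesign]], EffectTruth]:
    """Simulate the full multi-study panel: reference plus comparison models.

    Requires the config to name a reference study with rho = 1 and at
    least two comparison studies, so the model-ranking question is
    well-posed.
    """
    if config.reference not in config.rho:
        raise ValueError(f"reference {config.reference!r} not among studies {config.studies}")
    if config.rho[config.reference] != 1.0:
        raise ValueError(
            f"reference study {config.reference!r} must have rho = 1, "
            f"got {config.rho[config.reference]}"
        )
    if len(config.rho) < 3:
        raise ValueError("panel needs a reference and at least two comparison studies")
    truth = simulate_truth(config)
    studies = {s: simulate_counts(truth, config, s) for s in config.studies}
    return studies, truth
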