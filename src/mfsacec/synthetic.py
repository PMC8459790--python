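"""Synthetic expression data with known ground truth.

The generator plants a small block of differentially expressed genes in a
background of pure Gaussian noise genes.  For a sample of class c, an
informative gene g takes

    sign_g * (delta * sd * mu_c  +  sd * sqrt(rho) * z_s)  +  sd * sqrt(1 - rho) * eps,

where mu_c is the class offset (0, 1, ..., N-1), z_s a per-sample latent
factor shared by the whole signal block, and eps independent noise.  Each
informative gene therefore has unit-variance noise around a class mean
shifted by ``delta`` standard deviations, same-sign genes correlate at
``rho`` within a class, and opposite-sign genes correlate at ``-rho`` --
emulating positively and negatively co-expressed members of one pathway.
Noise genes are Normal(0, sd).  Class sizes may be unequal, exercising
the oversampling path.

The structure is deliberately minimal: no probe saturation, spatial
artifacts, heavy tails or batch effects, so passing tests demonstrate the
mechanics of the method, not robustness to real microarray noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionDataset

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "default_fixture", "DEFAULT_SPEC"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-signal generator.

    ``effect_size`` is the class-mean shift in units of ``noise_sd``;
    ``anti_correlated_fraction`` is the fraction of informative genes
    carrying the negated signal; ``block_correlation`` is the latent
    pairwise correlation among same-sign informative genes.
    """

    n_per_class: tuple[int, ...] = (40, 20)
    n_genes: int = 1000
    n_informative: int = 20
    effect_size: float = 3.0
    anti_correlated_fraction: float = 0.5
    noise_sd: float = 1.0
    block_correlation: float = 0.7
    seed: int = 101

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_class) or len(self.n_per_class) < 2:
            raise ValueError("need >= 2 classes with >= 1 sample each")
        if not (0 <= self.n_informative <= self.n_genes):
            raise ValueError("n_informative must be in 0..n_genes")
        if not (0.0 <= self.anti_correlated_fraction <= 1.0):
            raise ValueError("anti_correlated_fraction must be in [0, 1]")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ValueError("block_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Which genes carry signal, with what sign, and the class means."""

    informative: np.ndarray  # gene indices, sorted
    signs: np.ndarray        # +1 / -1 aligned with `informative`
    class_means: np.ndarray  # per class, the mean of a +1 informative gene

    @property
    def informative_ids(self) -> list[str]:
        return [f"g{int(i):04d}" for i in self.informative]


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset from the generator; fully determined by the seed."""
    rng = np.random.default_rng(spec.seed)
    n_classes = len(spec.n_per_class)
    u = int(sum(spec.n_per_class))
    y = np.repeat(np.arange(n_classes), spec.n_per_class)
    values = rng.normal(0.0, spec.noise_sd, size=(u, spec.n_genes))

    informative = np.sort(rng.choice(spec.n_genes, size=spec.n_informative, replace=False))
    n_neg = int(round(spec.anti_correlated_fraction * spec.n_informative))
    signs = np.ones(spec.n_informative, dtype=int)
    if n_neg:
        signs[-n_neg:] = -1

    delta = spec.effect_size * spec.noise_sd
    rho = spec.block_correlation
    latent = rng.normal(0.0, 1.0, size=u)
    for g, sign in zip(informative, signs):
        values[:, g] = (
            sign * (delta * y + spec.noise_sd * np.sqrt(rho) * latent)
            + np.sqrt(1.0 - rho) * values[:, g]
        )

    ds = ExpressionDataset(
        values=values,
        gene_ids=[f"g{i:04d}" for i in range(spec.n_genes)],
        sample_ids=[f"s{i:03d}" for i in range(u)],
        classes=np.array([f"class{c}" for c in y]),
    )
    truth = GroundTruth(
        informative=informative,
        signs=signs,
        class_means=delta * np.arange(n_classes, dtype=float),
    )
    return ds, truth


DEFAULT_SPEC = SyntheticSpec()


def default_fixture() -> tuple[ExpressionDataset, GroundTruth]:
    """The frozen reference fixture: 60 samples (40/20, imbalanced),
    1000 genes, 20 informative (half anti-correlated), effect size 3 SD,
    block correlation 0.7, fixed seed."""
    return generate(DEFAULT_SPEC)
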