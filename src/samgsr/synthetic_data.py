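"""Synthetic two-class expression studies with gene-set-structured signal.

The generator emulates the data the pipeline consumes: a log2-scale
genes x samples matrix for two balanced classes, a gene-set collection
covering part of the genome, and known ground truth. Each set has one
latent factor: a member gene is ``loading * factor + noise_sd * eps`` per
sample, which makes the within-set pairwise correlation
``loading^2 / (loading^2 + noise_sd^2)`` and the marginal variance
``loading^2 + noise_sd^2``. By default ``noise_sd = sqrt(1 - loading^2)``,
so genes have unit variance and the within-set correlation is exactly
``loading^2``. Genes outside every set are independent noise at the same
marginal variance.

Differential signal is planted on designated *core* genes of the first
``n_signal_sets`` sets: their diseased-class mean is shifted by
``effect_size`` marginal standard deviations, giving the reduction step a
known answer to recover.

Two-study mode re-draws new samples from the same factor model (coherent
genes) while a chosen fraction of genes is replaced in the second study by
independent noise (incoherent genes), emulating cross-platform
irreproducibility for the IC filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_data import (
    CONTROL,
    DISEASED,
    CountMatrix,
    ExpressionStudy,
    GeneSetCollection,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generation parameters.

    Defaults describe a desk-scale two-class cohort: 1,200 genes of which
    1,000 fall into twenty 50-gene sets (200 background genes belong to no
    set), two signal sets with five core genes each shifted by 1.5 SD,
    within-set correlation 0.36 (loading 0.6), and 30 samples per class.
    """

    n_genes: int = 1200
    n_sets: int = 20
    set_size: int = 50
    n_signal_sets: int = 2
    n_core_per_signal_set: int = 5
    effect_size: float = 1.5
    correlation: float = 0.6  # latent-factor loading, in [0, 1)
    n_per_class: int = 30
    noise_sd: float | None = None  # default sqrt(1 - loading^2)
    incoherent_fraction: float = 0.5  # two-study mode only
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_sets, self.set_size, self.n_per_class) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_signal_sets > self.n_sets:
            raise ValueError("n_signal_sets cannot exceed n_sets")
        if self.n_core_per_signal_set > self.set_size:
            raise ValueError("n_core_per_signal_set cannot exceed set_size")
        if self.n_sets * self.set_size > self.n_genes:
            raise ValueError("n_sets * set_size exceeds n_genes")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation (loading) must lie in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.incoherent_fraction <= 1.0:
            raise ValueError("incoherent_fraction must lie in [0, 1]")
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return math.sqrt(1.0 - self.correlation**2)

    @property
    def marginal_sd(self) -> float:
        return math.sqrt(self.correlation**2 + self.resolved_noise_sd**2)


def _gene_ids(n: int) -> tuple[str, ...]:
    width = max(4, len(str(n)))
    return tuple(f"g{i + 1:0{width}d}" for i in range(n))


def _layout(config: SimulationConfig):
    """Assign genes to sets; leftover genes are set-less background."""
    genes = _gene_ids(config.n_genes)
    sets: dict[str, tuple[str, ...]] = {}
    cores: dict[str, tuple[str, ...]] = {}
    cursor = 0
    for s in range(config.n_sets):
        members = genes[cursor : cursor + config.set_size]
        cursor += config.set_size
        name = f"SET{s + 1:02d}"
        sets[name] = members
        if s < config.n_signal_sets:
            cores[name] = members[: config.n_core_per_signal_set]
    background = genes[cursor:]
    return genes, sets, cores, background


def _labels(config: SimulationConfig) -> tuple[str, ...]:
    return (CONTROL,) * config.n_per_class + (DISEASED,) * config.n_per_class


def _draw_matrix(
    config: SimulationConfig,
    rng: np.random.Generator,
    sets: dict[str, tuple[str, ...]],
    background: Sequence[str],
    labels: Sequence[str],
    cores: dict[str, tuple[str, ...]],
    incoherent: frozenset[str] = frozenset(),
) -> np.ndarray:
    n = len(labels)
    loading = config.correlation
    sigma = config.resolved_noise_sd
    total_sd = config.marginal_sd
    diseased = np.array([c == DISEASED for c in labels])
    values = np.empty((config.n_genes, n))
    row = 0
    core_rows: list[int] = []
    incoherent_rows: list[int] = []
    for name, members in sets.items():
        factor = rng.standard_normal(n)
        noise = rng.standard_normal((len(members), n))
        block = loading * factor[None, :] + sigma * noise
        values[row : row + len(members)] = block
        core_members = set(cores.get(name, ()))
        for i, g in enumerate(members):
            if g in core_members:
                core_rows.append(row + i)
            if g in incoherent:
                incoherent_rows.append(row + i)
        row += len(members)
    if background:
        values[row : row + len(background)] = total_sd * rng.standard_normal(
            (len(background), n)
        )
        for i, g in enumerate(background):
            if g in incoherent:
                incoherent_rows.append(row + i)
        row += len(background)
    # incoherent genes lose their shared structure: independent redraw
    if incoherent_rows:
        values[incoherent_rows] = total_sd * rng.standard_normal(
            (len(incoherent_rows), n)
        )
    # plant the class effect on core genes (skip redrawn incoherent ones)
    shift_rows = sorted(set(core_rows) - set(incoherent_rows))
    if shift_rows and config.effect_size > 0:
        values[np.ix_(shift_rows, np.flatnonzero(diseased))] += (
            config.effect_size * total_sd
        )
    return values


def simulate_study(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, GeneSetCollection, dict]:
    """One labeled study, its gene-set collection, and the ground truth.

    Ground truth records the signal sets, their core genes, and the
    background (set-less) genes. Identical configs (same seed) produce
    byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    genes, sets, cores, background = _layout(config)
    labels = _labels(config)
    values = _draw_matrix(config, rng, sets, background, labels, cores)
    sample_ids = tuple(f"s{i + 1:03d}" for i in range(len(labels)))
    study = ExpressionStudy(genes, sample_ids, values, labels)
    collection = GeneSetCollection(
        dict(sets), provenance=f"simulated (seed={config.seed})"
    )
    truth = {
        "signal_sets": sorted(cores),
        "core_genes": {k: list(v) for k, v in cores.items()},
        "background_genes": list(background),
    }
    return study, collection, truth


def simulate_paired_studies(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, ExpressionStudy, dict]:
    """Two studies sharing factor structure except for planted incoherence.

    Study 1 is exactly :func:`simulate_study`'s output for this config.
    Study 2 draws fresh samples with the same set layout and loadings, but
    an ``incoherent_fraction`` of genes (chosen uniformly) is replaced by
    independent noise, so their co-expression pattern no longer matches
    study 1. Ground truth lists the incoherent genes.
    """
    rng = np.random.default_rng(config.seed)
    genes, sets, cores, background = _layout(config)
    labels = _labels(config)
    values1 = _draw_matrix(config, rng, sets, background, labels, cores)
    n_inc = int(round(config.incoherent_fraction * config.n_genes))
    incoherent = frozenset(
        genes[i]
        for i in sorted(rng.choice(config.n_genes, size=n_inc, replace=False))
    )
    values2 = _draw_matrix(
        config, rng, sets, background, labels, cores, incoherent=incoherent
    )
    sample_ids1 = tuple(f"s{i + 1:03d}" for i in range(len(labels)))
    sample_ids2 = tuple(f"t{i + 1:03d}" for i in range(len(labels)))
    study1 = ExpressionStudy(genes, sample_ids1, values1, labels)
    study2 = ExpressionStudy(genes, sample_ids2, values2, labels)
    truth = {
        "incoherent_genes": sorted(incoherent),
        "coherent_genes": sorted(set(genes) - incoherent),
        "signal_sets": sorted(cores),
        "core_genes": {k: list(v) for k, v in cores.items()},
    }
    return study1, study2, truth


def simulate_counts(
    config: SimulationConfig, mean_library: float = 1e6
) -> CountMatrix:
    """Rough count-scale companion for exercising the CPM+log2 utility.

    Counts are Poisson draws around per-gene abundances exponentiated from a
    simulated log2 study. Not calibrated to real RNA-seq dispersion — it
    exists so the count path is testable end to end.
    """
    study, _, _ = simulate_study(config)
    rng = np.random.default_rng(config.seed + 1)
    rel = 2.0 ** (study.values + 4.0)
    rel /= rel.sum(axis=0, keepdims=True)
    lam = rel * mean_library
    counts = rng.poisson(lam)
    return CountMatrix(study.gene_ids, study.sample_ids, counts)
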