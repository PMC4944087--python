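"""Integrative-correlation filtering of cross-study incoherent genes.

For two studies sharing a gene universe, each gene k gets a vector of
Pearson correlations with every other common gene, computed within each
study separately; the gene's integrative-correlation (IC) score is the
Pearson correlation between its two vectors. A gene whose co-expression
neighbourhood looks nothing alike across platforms — IC near or below
zero — is likely noise, and the default filter drops every gene whose IC
falls strictly below the median IC (so roughly half the universe is kept,
and genes exactly at the median survive).

The all-pairs computation runs as standardized-matrix products in row
blocks, so the two G x G correlation matrices are never materialized at
once; 7,000 genes x 100 samples fits comfortably in memory and minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_data import ExpressionStudy
from .errors import DataError

logger = logging.getLogger("samgsr")


@dataclass(frozen=True)
class ICResult:
    """Per-gene IC scores over the common universe plus the filter verdict."""

    gene_ids: tuple[str, ...]
    ic_scores: np.ndarray
    threshold: float
    kept_genes: tuple[str, ...]
    dropped_genes: tuple[str, ...]

    def __post_init__(self):
        scores = np.asarray(self.ic_scores, dtype=float)
        object.__setattr__(self, "ic_scores", scores)
        if scores.shape != (len(self.gene_ids),):
            raise ValueError("one IC score per gene required")
        if np.any(scores < -1 - 1e-9) or np.any(scores > 1 + 1e-9):
            raise ValueError("IC scores must lie in [-1, 1]")
        if set(self.kept_genes) | set(self.dropped_genes) != set(self.gene_ids):
            raise ValueError("kept and dropped must partition the universe")
        if set(self.kept_genes) & set(self.dropped_genes):
            raise ValueError("kept and dropped must be disjoint")


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and unit-normalize rows; zero-variance rows become all-zero."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return centered / safe[:, None], zero


def _row_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between matching rows of two matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    denom = na * nb
    out = np.zeros(a.shape[0])
    good = denom > 0
    out[good] = np.einsum("ij,ij->i", ac[good], bc[good]) / denom[good]
    return np.clip(out, -1.0, 1.0)


def integrative_correlation(
    study1: ExpressionStudy,
    study2: ExpressionStudy,
    block_size: int = 512,
) -> ICResult:
    """IC score for every gene common to both studies.

    The common universe is the ID intersection in ``study1``'s gene order.
    For gene k the pair vector holds its correlations with every other
    common gene (self excluded). Genes with zero variance in either study —
    whose correlations are undefined — receive IC 0 (maximally incoherent)
    with a warning, which errs toward removal by the median filter.
    """
    for s, tag in ((study1, "study1"), (study2, "study2")):
        if s.n_samples < 3:
            raise DataError(f"{tag}: need >= 3 samples for IC")
    common = [g for g in study1.gene_ids if g in set(study2.gene_ids)]
    if len(common) < 3:
        raise DataError(
            f"only {len(common)} common genes; need >= 3 "
            "(check gene-ID namespaces)"
        )
    x1 = study1.subset_genes(common).values
    x2 = study2.subset_genes(common).values
    z1, zero1 = _standardize_rows(x1)
    z2, zero2 = _standardize_rows(x2)
    degenerate = zero1 | zero2
    if degenerate.any():
        names = [common[i] for i in np.flatnonzero(degenerate)]
        logger.warning(
            "zero-variance gene(s) get IC 0: %s", ", ".join(names[:20])
        )

    G = len(common)
    scores = np.zeros(G)
    for start in range(0, G, block_size):
        stop = min(start + block_size, G)
        c1 = z1[start:stop] @ z1.T  # (b, G) correlation rows in study1
        c2 = z2[start:stop] @ z2.T
        # drop the self-correlation entry from each row
        rows = np.arange(stop - start)
        cols = np.arange(start, stop)
        mask = np.ones((stop - start, G), dtype=bool)
        mask[rows, cols] = False
        v1 = c1[mask].reshape(stop - start, G - 1)
        v2 = c2[mask].reshape(stop - start, G - 1)
        scores[start:stop] = _row_correlation(v1, v2)
    scores[degenerate] = 0.0

    threshold, keep_mask = median_partition(scores)
    kept = tuple(g for g, k in zip(common, keep_mask) if k)
    dropped = tuple(g for g, k in zip(common, keep_mask) if not k)
    return ICResult(
        gene_ids=tuple(common),
        ic_scores=scores,
        threshold=threshold,
        kept_genes=kept,
        dropped_genes=dropped,
    )


def median_partition(scores: np.ndarray) -> tuple[float, np.ndarray]:
    """Strict median rule: (median, keep mask), dropping scores < median.

    At even counts the median is the midpoint of the two central order
    statistics; scores exactly at the median are kept, so all-equal scores
    drop nothing.
    """
    scores = np.asarray(scores, dtype=float)
    threshold = float(np.median(scores))
    return threshold, scores >= threshold


def apply_ic_filter(result: ICResult, study: ExpressionStudy) -> ExpressionStudy:
    """Restrict a study to the genes the IC median rule keeps.

    The rule is strict: only genes with IC strictly below the median are
    dropped, so ties at the median survive (with all-equal scores nothing is
    dropped).
    """
    keep = [g for g in study.gene_ids if g in set(result.kept_genes)]
    if not keep:
        raise DataError("no kept gene present in the study")
    return study.subset_genes(keep)


def write_ic_table(result: ICResult, path) -> None:
    """TSV report: gene_id, ic_score, kept flag."""
    kept = set(result.kept_genes)
    with open(path, "w") as fh:
        fh.write("gene_id\tic_score\tkept\n")
        for g, s in zip(result.gene_ids, result.ic_scores):
            fh.write(f"{g}\t{s:.10g}\t{int(g in kept)}\n")
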