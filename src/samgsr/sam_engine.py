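"""SAM statistics, the set-level SAMGS statistic, and permutation significance.

The per-gene statistic is the SAM moderated two-group statistic

    d_i = (mean_diseased_i - mean_control_i) / (s_i + s0)

where ``s_i`` is the gene-specific scatter of the SAM denominator — the
pooled standard error of the mean difference,
``sqrt((1/n_d + 1/n_c) * SS_pooled / (n_d + n_c - 2))`` — and ``s0`` is a
small positive "fudge" constant that damps the statistic for genes with tiny
variance. The set-level statistic is the squared L2 norm of the members'
SAM statistics::

    SAMGS_j = sum_{i in j} d_i^2

Significance is assessed by permuting phenotype labels: the same B permuted
label vectors (a :class:`PermutationScheme`) are reused for every set and for
every reduction step, so work scales as B x genes rather than
B x sets x genes and p-values are comparable across sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

from .core_data import ExpressionStudy, DISEASED
from .errors import ClassSizeError, EnumerationTooLargeError, SchemeMismatchError

__all__ = [
    "SamProfile",
    "PermutationScheme",
    "GeneSetScore",
    "estimate_s0",
    "compute_sam",
    "samgs_statistic",
    "build_permutation_scheme",
    "PermutationEngine",
    "permutation_pvalue",
    "exact_enumeration_pvalue",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamProfile:
    """Per-gene SAM statistics for one labeling of one study."""

    d: np.ndarray
    mean_diff: np.ndarray
    pooled_sd: np.ndarray
    s0: float

    def __post_init__(self):
        if self.s0 < 0:
            raise ValueError("s0 must be nonnegative")
        if np.any(self.pooled_sd < 0):
            raise ValueError("pooled_sd must be nonnegative")
        if self.s0 == 0 and np.any(self.pooled_sd == 0):
            raise ValueError("s0 must be > 0 when any pooled_sd is 0")


@dataclass(frozen=True)
class PermutationScheme:
    """B class-size-preserving label shuffles over a study's samples.

    ``label_matrix`` is a (B, n_samples) boolean array, True marking the
    samples assigned to the diseased group in that permutation. Identical
    seeds yield identical matrices.
    """

    n_perm: int
    seed: int
    label_matrix: np.ndarray

    def __post_init__(self):
        lm = np.asarray(self.label_matrix, dtype=bool)
        object.__setattr__(self, "label_matrix", lm)
        if lm.shape[0] != self.n_perm:
            raise ValueError("label_matrix must have n_perm rows")
        counts = lm.sum(axis=1)
        if lm.size and not np.all(counts == counts[0]):
            raise ValueError("permutations must preserve class sizes")

    @property
    def n_samples(self) -> int:
        return self.label_matrix.shape[1]


@dataclass(frozen=True)
class GeneSetScore:
    set_name: str
    samgs: float
    p_value: float

    def __post_init__(self):
        if self.samgs < 0:
            raise ValueError("SAMGS is a sum of squares; must be >= 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# SAM statistics
# ---------------------------------------------------------------------------

def _group_stats(values: np.ndarray, diseased: np.ndarray):
    """Mean difference and SAM denominator scatter for one label vector."""
    n_d = int(diseased.sum())
    n_c = diseased.size - n_d
    if n_d < 2 or n_c < 2:
        raise ClassSizeError(f"need >= 2 samples per class; got {n_d} vs {n_c}")
    xd = values[:, diseased]
    xc = values[:, ~diseased]
    mean_d = xd.mean(axis=1)
    mean_c = xc.mean(axis=1)
    ss = ((xd - mean_d[:, None]) ** 2).sum(axis=1) + (
        (xc - mean_c[:, None]) ** 2
    ).sum(axis=1)
    a = (1.0 / n_d + 1.0 / n_c) / (n_d + n_c - 2)
    pooled_sd = np.sqrt(np.maximum(a * ss, 0.0))
    return mean_d - mean_c, pooled_sd


def estimate_s0(mean_diff: np.ndarray, pooled_sd: np.ndarray, n_bins: int = 10) -> float:
    """Estimate the fudge constant by the original SAM recipe.

    Candidates are the percentiles {0, 5, ..., 100} of the gene-wise scatter
    ``pooled_sd``; for each candidate the genes are binned by scatter
    quantile and the candidate minimizing the coefficient of variation of
    the per-bin median absolute deviation of ``d`` is chosen. If the winner
    is 0 while some gene has zero scatter, the smallest positive candidate
    (or a small floor) is used instead so d stays finite.
    """
    s = np.asarray(pooled_sd, dtype=float)
    if s.size < 2:
        return float(max(s.max(initial=0.0), 1.0)) * 0.01 or 1e-8
    candidates = np.percentile(s, np.arange(0, 101, 5))
    n_bins = min(n_bins, max(2, s.size // 5))
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    best_s0, best_cv = None, np.inf
    for s0 in candidates:
        d = mean_diff / (s + s0) if s0 > 0 else _safe_ratio(mean_diff, s)
        mads = []
        for b in range(n_bins):
            db = d[bins == b]
            if db.size:
                mads.append(np.median(np.abs(db - np.median(db))))
        mads = np.asarray(mads)
        if mads.size < 2 or not np.all(np.isfinite(mads)) or mads.mean() == 0:
            continue
        cv = mads.std() / mads.mean()
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    if best_s0 is None:
        best_s0 = float(np.median(s))
    if best_s0 == 0.0 and np.any(s == 0):
        positive = candidates[candidates > 0]
        best_s0 = float(positive.min()) if positive.size else 1e-8
    return best_s0


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full_like(num, np.inf)
    np.divide(num, den, out=out, where=den > 0)
    out[(den == 0) & (num == 0)] = 0.0
    return out


def compute_sam(
    study: ExpressionStudy,
    labels: Sequence[str] | None = None,
    s0: float | None = None,
) -> SamProfile:
    """Per-gene SAM statistics for a study under the given (or its own) labels.

    With ``s0=None`` the fudge constant is estimated by :func:`estimate_s0`.
    """
    if labels is not None:
        diseased = np.array([c == DISEASED for c in labels], dtype=bool)
        if diseased.size != study.n_samples:
            raise ValueError("labels length must match sample count")
    else:
        diseased = study.label_indicator()
    mean_diff, pooled_sd = _group_stats(study.values, diseased)
    if s0 is None:
        s0 = estimate_s0(mean_diff, pooled_sd)
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    if s0 == 0 and np.any(pooled_sd == 0):
        raise ValueError("s0 must be positive when a gene has zero pooled SD")
    d = mean_diff / (pooled_sd + s0)
    return SamProfile(d=d, mean_diff=mean_diff, pooled_sd=pooled_sd, s0=float(s0))


def samgs_statistic(profile: SamProfile, member_indices: Sequence[int]) -> float:
    """Squared L2 norm of the members' SAM statistics."""
    idx = np.asarray(member_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("member_indices must be nonempty")
    if idx.min() < 0 or idx.max() >= self_len(profile):
        raise IndexError("member index out of range")
    return float(np.sum(profile.d[idx] ** 2))


def self_len(profile: SamProfile) -> int:
    return profile.d.shape[0]


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def build_permutation_scheme(
    labels: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationScheme:
    """Draw B label shuffles preserving the two class sizes."""
    diseased = np.array([c == DISEASED for c in labels], dtype=bool)
    rng = np.random.default_rng(seed)
    lm = np.empty((n_perm, diseased.size), dtype=bool)
    for b in range(n_perm):
        lm[b] = rng.permutation(diseased)
    return PermutationScheme(n_perm=n_perm, seed=seed, label_matrix=lm)


def _tie_floor(obs):
    """Comparison floor so numerically tied permutations count as >= observed.

    The observed and permuted statistics come from algebraically equivalent
    but differently rounded paths; ties must count against the observed
    (conservative), so the threshold sits a hair below it.
    """
    return obs - (1e-9 * np.abs(obs) + 1e-12)


def _sam_d_matrix(values: np.ndarray, label_matrix: np.ndarray, s0: float) -> np.ndarray:
    """d statistics for every gene under every permuted labeling.

    Vectorized over permutations: returns a (G, B) matrix. Uses the sum-of-
    squares identity SS = sum(x^2) - n_d*mean_d^2 - n_c*mean_c^2.
    """
    Z = label_matrix.astype(float)  # (B, n)
    n_d = label_matrix[0].sum()
    n_c = label_matrix.shape[1] - n_d
    n = n_d + n_c
    row_sum = values.sum(axis=1)  # (G,)
    row_sq = (values**2).sum(axis=1)  # (G,)
    S1 = values @ Z.T  # (G, B) sums over diseased
    mean_d = S1 / n_d
    mean_c = (row_sum[:, None] - S1) / n_c
    ss = row_sq[:, None] - n_d * mean_d**2 - n_c * mean_c**2
    a = (1.0 / n_d + 1.0 / n_c) / (n - 2)
    pooled_sd = np.sqrt(np.maximum(a * ss, 0.0))
    return (mean_d - mean_c) / (pooled_sd + s0)


class PermutationEngine:
    """Observed SAM profile plus the permuted per-gene d^2 matrix for a study.

    Built once per (study, scheme) pair and shared by every set-level test
    and every reduction step: the SAMGS null statistic of any member subset
    is a column-subset sum of ``perm_d2``.

    ``s0_policy`` is ``"fixed"`` (default: s0 estimated once from the
    observed labels and held fixed under permutation) or ``"re-estimated"``
    (s0 re-estimated for each permuted labeling).
    """

    def __init__(
        self,
        study: ExpressionStudy,
        scheme: PermutationScheme,
        s0: float | None = None,
        s0_policy: str = "fixed",
    ):
        if scheme.n_samples != study.n_samples:
            raise SchemeMismatchError(
                f"scheme built for {scheme.n_samples} samples; "
                f"study has {study.n_samples}"
            )
        if s0_policy not in {"fixed", "re-estimated"}:
            raise ValueError("s0_policy must be 'fixed' or 're-estimated'")
        self.study = study
        self.scheme = scheme
        self.profile = compute_sam(study, s0=s0)
        if s0_policy == "fixed":
            d_perm = _sam_d_matrix(
                study.values, scheme.label_matrix, self.profile.s0
            )
        else:
            cols = []
            for b in range(scheme.n_perm):
                diseased = scheme.label_matrix[b]
                md, sd = _group_stats(study.values, diseased)
                cols.append(md / (sd + estimate_s0(md, sd)))
            d_perm = np.column_stack(cols)
        self.perm_d2 = d_perm**2  # (G, B)
        self.obs_d2 = self.profile.d**2

    @property
    def n_perm(self) -> int:
        return self.scheme.n_perm

    def set_pvalue(self, member_indices: Sequence[int]) -> tuple[float, float]:
        """(SAMGS observed, add-one permutation p-value) for one member list."""
        idx = np.asarray(member_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("member_indices must be nonempty")
        obs = float(self.obs_d2[idx].sum())
        null = self.perm_d2[idx].sum(axis=0)
        p = (1.0 + np.count_nonzero(null >= _tie_floor(obs))) / (1.0 + self.n_perm)
        return obs, float(p)

    def suffix_pvalues(self, ordered_indices: np.ndarray) -> np.ndarray:
        """p-values of the complements left after removing 1..m-1 top genes.

        For genes given in reduction order, entry k-1 is the add-one
        permutation p-value of the SAMGS statistic of genes k..m-1 (the
        complement after removing the top k). Length m-1; the empty
        complement's p-value (defined as 1) is appended by the caller.
        """
        obs = self.obs_d2[ordered_indices]  # (m,)
        null = self.perm_d2[ordered_indices]  # (m, B)
        # suffix sums excluding the first k entries, k = 1..m-1
        obs_suffix = obs[::-1].cumsum()[::-1]  # obs_suffix[k] = sum_{i>=k}
        null_suffix = null[::-1].cumsum(axis=0)[::-1]
        exceed = (null_suffix[1:] >= _tie_floor(obs_suffix[1:, None])).sum(axis=1)
        return (1.0 + exceed) / (1.0 + self.n_perm)


def permutation_pvalue(
    study: ExpressionStudy,
    member_indices: Sequence[int],
    scheme: PermutationScheme,
    s0: float | None = None,
    s0_policy: str = "fixed",
    set_name: str = "",
) -> GeneSetScore:
    """Monte-Carlo SAMGS significance for one gene set.

    p = (1 + #{b : SAMGS_b >= SAMGS_obs}) / (1 + B) — the add-one convention,
    so p is never 0 and ties count against the observed statistic.
    """
    engine = PermutationEngine(study, scheme, s0=s0, s0_policy=s0_policy)
    obs, p = engine.set_pvalue(member_indices)
    return GeneSetScore(set_name=set_name, samgs=obs, p_value=p)


def exact_enumeration_pvalue(
    study: ExpressionStudy,
    member_indices: Sequence[int],
    s0: float | None = None,
    max_assignments: int = 10_000,
) -> float:
    """Exact permutation p-value by enumerating all label assignments.

    Every class-size-preserving assignment of samples to groups is scored;
    the observed assignment is part of the null set, so p >= 1/#assignments.
    Intended as a small-sample oracle for the Monte-Carlo path.
    """
    diseased = study.label_indicator()
    n = diseased.size
    n_d = int(diseased.sum())
    total = comb(n, n_d)
    if total > max_assignments:
        raise EnumerationTooLargeError(
            f"{total} assignments exceed cap {max_assignments}; "
            "use the Monte-Carlo path"
        )
    idx = np.asarray(member_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("member_indices must be nonempty")
    profile = compute_sam(study, s0=s0)
    obs = float(np.sum(profile.d[idx] ** 2))
    lm = np.zeros((total, n), dtype=bool)
    for b, combo in enumerate(itertools.combinations(range(n), n_d)):
        lm[b, list(combo)] = True
    d = _sam_d_matrix(study.values[idx], lm, profile.s0)
    null = (d**2).sum(axis=0)
    return float(np.count_nonzero(null >= _tie_floor(obs)) / total)
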