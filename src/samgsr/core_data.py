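"""Data model and I/O for expression matrices, labels and gene-set collections.

Conventions used throughout the package:

* expression matrices are **genes as rows, samples as columns**, on log2 scale;
* phenotype labels are the two literals ``"diseased"`` and ``"control"``;
* expression files are TSV with a ``gene_id`` first column and sample IDs in
  the header; labels files are two-column TSV ``sample_id<TAB>class``;
* gene sets travel in GMT (one set per line: name, description, members).

Two normalization utilities are included: a counts-per-million + log2
transform for sequencing read counts (the voom transform without its
precision weights, which nothing downstream consumes) and quantile
normalization across samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    ClassSizeError,
    EmptyMappingError,
    GmtFormatError,
    DuplicateSetNameError,
    MalformedHeaderError,
    MissingLabelError,
    NonNumericValueError,
    UnknownSampleError,
    ZeroLibraryError,
)

logger = logging.getLogger("samgsr")

DISEASED = "diseased"
CONTROL = "control"
CLASSES = (CONTROL, DISEASED)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionStudy:
    """A log2-scale expression matrix with optional binary phenotype labels.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``; all
        entries finite.
    labels
        Optional per-sample class, each ``"diseased"`` or ``"control"``.
        When present, both classes must have at least two samples so the
        pooled standard deviation is estimable.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        gene_ids = tuple(str(g) for g in self.gene_ids)
        sample_ids = tuple(str(s) for s in self.sample_ids)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "values", values)
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample IDs")
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(gene_ids)}, {len(sample_ids)})"
            )
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if self.labels is not None:
            labels = tuple(str(c) for c in self.labels)
            object.__setattr__(self, "labels", labels)
            if len(labels) != len(sample_ids):
                raise ValueError("one label per sample required")
            bad = sorted(set(labels) - set(CLASSES))
            if bad:
                raise ValueError(f"labels must be in {CLASSES}; got {bad}")
            for cls in CLASSES:
                if labels.count(cls) < 2:
                    raise ClassSizeError(
                        f"class {cls!r} has {labels.count(cls)} samples; "
                        "need >= 2 (pooled SD must be estimable)"
                    )

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in study") from None

    def label_indicator(self) -> np.ndarray:
        """Boolean vector, True for diseased samples."""
        if self.labels is None:
            raise ValueError("study has no labels")
        return np.array([c == DISEASED for c in self.labels], dtype=bool)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionStudy":
        idx = self.gene_index(genes)
        return replace(self, gene_ids=tuple(genes), values=self.values[idx])

    def subset_samples(self, index: Sequence[int]) -> "ExpressionStudy":
        index = np.asarray(index, dtype=int)
        labels = None
        if self.labels is not None:
            labels = tuple(self.labels[i] for i in index)
        return replace(
            self,
            sample_ids=tuple(self.sample_ids[i] for i in index),
            values=self.values[:, index],
            labels=labels,
        )

    def with_labels(self, labels: Sequence[str]) -> "ExpressionStudy":
        return replace(self, labels=tuple(labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT-backed), optionally mapped onto a study.

    ``report`` records, after :func:`map_sets_to_study`, which sets were kept
    or dropped and each kept set's coverage fraction.
    """

    sets: dict[str, tuple[str, ...]]
    provenance: str = ""
    report: dict | None = None

    def __post_init__(self):
        clean: dict[str, tuple[str, ...]] = {}
        for name, members in self.sets.items():
            members = tuple(str(m) for m in members)
            if len(set(members)) != len(members):
                raise ValueError(f"set {name!r} has duplicate members")
            clean[str(name)] = members
        object.__setattr__(self, "sets", clean)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.sets)


@dataclass(frozen=True)
class CountMatrix:
    """Nonnegative read counts, genes as rows."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape mismatch")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    labels_path: str | Path | None = None,
    *,
    require_labels: bool = False,
    duplicate_policy: str = "max_variance",
) -> ExpressionStudy:
    """Read a genes-by-samples TSV, optionally with a sample-labels TSV.

    The first column must be ``gene_id``; the header row holds sample IDs.
    Duplicate gene IDs are collapsed by keeping the highest-variance row
    (``duplicate_policy="max_variance"``, the common expression-matrix
    convention) or by averaging (``"mean"``); either way a warning names the
    collapsed IDs.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    fields = header.split("\t")
    if len(fields) < 2 or fields[0].lower() not in {"gene_id", "gene", "id", ""}:
        raise MalformedHeaderError(
            f"{path}: expected header 'gene_id<TAB>sample...'; got {fields[:3]!r}"
        )
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise NonNumericValueError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.all(np.isfinite(values)):
        raise NonNumericValueError(f"{path}: non-finite value in matrix")

    gene_ids = df.index.astype(str)
    if gene_ids.duplicated().any():
        dupes = sorted(set(gene_ids[gene_ids.duplicated()]))
        if duplicate_policy == "max_variance":
            variances = values.var(axis=1)
            order = np.lexsort((-variances, gene_ids.to_numpy()))
            keep_mask = ~pd.Index(gene_ids[order]).duplicated()
            keep = np.sort(order[keep_mask])
            values = values[keep]
            gene_ids = gene_ids[keep]
        elif duplicate_policy == "mean":
            df = pd.DataFrame(values, index=gene_ids).groupby(level=0, sort=False).mean()
            gene_ids = df.index
            values = df.to_numpy()
        else:
            raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
        logger.warning(
            "collapsed duplicate gene IDs (%s policy): %s",
            duplicate_policy,
            ", ".join(dupes),
        )

    sample_ids = [str(c) for c in df.columns]
    labels = None
    if labels_path is not None:
        mapping = read_labels(labels_path)
        unknown = sorted(set(mapping) - set(sample_ids))
        if unknown:
            raise UnknownSampleError(
                f"{labels_path}: label(s) for unknown sample(s): {', '.join(unknown)}"
            )
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise MissingLabelError(
                f"{labels_path}: no label for sample(s): {', '.join(missing)}"
            )
        labels = tuple(mapping[s] for s in sample_ids)
    elif require_labels:
        raise MissingLabelError("labels required but no labels file given")
    return ExpressionStudy(tuple(gene_ids), tuple(sample_ids), values, labels)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>class`` TSV into a mapping."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in {"sample_id", "sample"}:
                continue
            if len(parts) != 2:
                raise MalformedHeaderError(
                    f"{path}:{lineno}: expected 'sample_id<TAB>class'"
                )
            mapping[parts[0]] = parts[1]
    return mapping


def write_expression(study: ExpressionStudy, path: str | Path) -> None:
    """Write a study as TSV at full precision (text round trip is exact to
    >= 12 significant digits)."""
    df = study.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_labels(study: ExpressionStudy, path: str | Path) -> None:
    if study.labels is None:
        raise ValueError("study has no labels to write")
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\n")
        for s, c in zip(study.sample_ids, study.labels):
            fh.write(f"{s}\t{c}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then members.

    Duplicate members within a line are dropped with a warning; a repeated
    set name is an error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtFormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, _desc, *members = parts
            if name in sets:
                raise DuplicateSetNameError(
                    f"{path}:{lineno}: duplicate set name {name!r}"
                )
            seen: dict[str, None] = {}
            dupes = []
            for m in members:
                if m in seen:
                    dupes.append(m)
                else:
                    seen[m] = None
            if dupes:
                logger.warning(
                    "%s:%d: set %s lists duplicate member(s): %s",
                    path, lineno, name, ", ".join(sorted(set(dupes))),
                )
            sets[name] = tuple(seen)
    return GeneSetCollection(sets, provenance=str(path))


def write_gmt(sets: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets:
            fh.write("\t".join([name, description, *members]) + "\n")


def write_sets_json(sets: GeneSetCollection, path: str | Path) -> None:
    """JSON mirror of a gene-set collection, for downstream tooling."""
    payload = {
        "provenance": sets.provenance,
        "sets": {name: list(members) for name, members in sets},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# set mapping and normalization
# ---------------------------------------------------------------------------

def map_sets_to_study(
    sets: GeneSetCollection,
    study: ExpressionStudy,
    min_set_size: int = 2,
) -> GeneSetCollection:
    """Intersect every set with the study's gene universe.

    Sets retaining fewer than ``min_set_size`` members are dropped. The
    returned collection carries a mapping report (kept/dropped names and
    per-set coverage). An empty result raises :class:`EmptyMappingError`.
    """
    if min_set_size < 2:
        raise ValueError("min_set_size must be >= 2")
    universe = set(study.gene_ids)
    kept: dict[str, tuple[str, ...]] = {}
    coverage: dict[str, float] = {}
    dropped: list[str] = []
    for name, members in sets:
        present = tuple(m for m in members if m in universe)
        if len(present) >= min_set_size:
            kept[name] = present
            coverage[name] = len(present) / len(members)
        else:
            dropped.append(name)
    if not kept:
        raise EmptyMappingError(
            "no gene set overlaps the study's gene universe by >= "
            f"{min_set_size} genes; check that gene-ID namespaces match"
        )
    report = {
        "kept": sorted(kept),
        "dropped": dropped,
        "coverage": coverage,
        "min_set_size": min_set_size,
    }
    return GeneSetCollection(kept, provenance=sets.provenance, report=report)


def cpm_log2(counts: CountMatrix, prior: float = 0.5) -> ExpressionStudy:
    """Counts-per-million on log2 scale.

    Each entry becomes ``log2((count + prior) / (library + 2*prior) * 1e6)``
    where ``library`` is the column sum — the voom transform's expression
    values, without its precision weights.
    """
    if prior <= 0:
        raise ValueError("prior must be > 0")
    libsize = counts.counts.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        names = ", ".join(counts.sample_ids[i] for i in zero)
        raise ZeroLibraryError(f"zero library size for sample(s): {names}")
    values = np.log2((counts.counts + prior) / (libsize + 2 * prior) * 1e6)
    return ExpressionStudy(counts.gene_ids, counts.sample_ids, values)


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Force every sample onto the common (mean) quantile distribution.

    The reference is the row-wise mean of the per-sample sorted values; ties
    within a sample map to the average of the reference values over the tied
    ranks (fractional ranks are linearly interpolated).
    """
    if study.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = study.values
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(study.n_genes, dtype=float)
    for j in range(study.n_samples):
        ranks = rankdata(x[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, reference)
    return replace(study, values=out)
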