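"""Core data containers for transcriptomic prediction.

Holds the line-by-gene expression matrix, per-line phenotypes, gene-set
(GO term) collections and the transcriptomic relationship matrix (TRM),
together with the file I/O and the centering/standardization transforms
every downstream model consumes.

Conventions
-----------
* Expression TSV: first column ``line_id``, remaining columns are gene IDs,
  one row per inbred line, no missing cells.
* Phenotype TSV: columns ``line_id`` and ``value`` (line means, trait units).
* Gene sets: standard GMT (``term_id <TAB> description <TAB> gene1 ...``).
* Standardization uses the sample variance (denominator ``n - 1``), which
  makes ``trace(TRM) = n - 1`` an exact identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "StandardizedExpression",
    "Phenotype",
    "GeneSetCollection",
    "KernelMatrix",
    "load_expression",
    "load_phenotype",
    "align",
    "standardize",
    "build_trm",
    "go_kernels",
    "partition_genes",
    "load_genesets",
]


@dataclass
class ExpressionMatrix:
    """n lines x m genes expression values with row/column identifiers."""

    values: np.ndarray
    line_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = list(self.line_ids)
        self.gene_ids = list(self.gene_ids)
        n, m = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 lines")
        if m < 1:
            raise ValueError("need at least 1 gene")
        if len(self.line_ids) != n or len(self.gene_ids) != m:
            raise ValueError("ID lengths do not match matrix shape")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line IDs")
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionMatrix(self.values[:, idx], self.line_ids, list(genes))

    def subset_lines(self, indices: np.ndarray) -> "ExpressionMatrix":
        indices = np.asarray(indices)
        return ExpressionMatrix(
            self.values[indices], [self.line_ids[i] for i in indices], self.gene_ids
        )


@dataclass
class StandardizedExpression:
    """Column-standardized expression W (mean 0, unit sample variance).

    ``col_means``/``col_sds`` are the training statistics so held-out lines
    can be projected onto the same scale via :meth:`transform`.
    """

    values: np.ndarray
    line_ids: list[str]
    gene_ids: list[str]
    col_means: np.ndarray
    col_sds: np.ndarray
    excluded_genes: list[str] = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def transform(self, expr: ExpressionMatrix) -> np.ndarray:
        """Project new lines onto this standardization (training stats)."""
        idx = [expr.gene_ids.index(g) for g in self.gene_ids]
        return (expr.values[:, idx] - self.col_means) / self.col_sds


@dataclass
class Phenotype:
    """Per-line trait values (line means), aligned to an expression matrix."""

    values: np.ndarray
    line_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.line_ids = list(self.line_ids)
        if len(self.values) != len(self.line_ids):
            raise ValueError("value/ID length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype contains missing/non-finite values")


@dataclass
class GeneSetCollection:
    """Named gene sets (GO terms) restricted to an expression gene universe."""

    sets: dict[str, list[str]]
    min_size: int = 5

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if len(members) < self.min_size:
                raise ValueError(
                    f"set {term} has {len(members)} members < min_size {self.min_size}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term: str) -> bool:
        return term in self.sets

    def __getitem__(self, term: str) -> list[str]:
        return self.sets[term]

    def terms(self) -> list[str]:
        return list(self.sets)


@dataclass
class KernelMatrix:
    """Symmetric PSD n x n similarity kernel among lines.

    ``scale_m`` is the number of genes the cross-products were averaged over
    (the *total* gene count for GO-partitioned kernels, so partitioned blocks
    sum to the full TRM).
    """

    values: np.ndarray
    scale_m: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel must be square")
        asym = np.max(np.abs(self.values - self.values.T))
        if asym > 1e-10:
            raise ValueError(f"kernel not symmetric (max asymmetry {asym:.2e})")

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# I/O


def load_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "line_id":
        raise ValueError(f"first column must be 'line_id', got {df.columns[0]!r}")
    if df.isna().any().any():
        raise ValueError("expression TSV has missing cells")
    return ExpressionMatrix(
        df.iloc[:, 1:].to_numpy(dtype=float),
        df["line_id"].tolist(),
        df.columns[1:].tolist(),
    )


def load_phenotype(path) -> Phenotype:
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    for col in ("line_id", "value"):
        if col not in df.columns:
            raise ValueError(f"phenotype TSV missing column {col!r}")
    if df[["line_id", "value"]].isna().any().any():
        raise ValueError("phenotype TSV has missing cells")
    return Phenotype(df["value"].to_numpy(dtype=float), df["line_id"].tolist())


def align(
    expr: ExpressionMatrix, pheno: Phenotype, drop_unmatched: bool = False
) -> tuple[ExpressionMatrix, Phenotype]:
    """Join expression and phenotype by line ID, preserving expression order.

    By default any line present in one input but not the other is a hard
    error; ``drop_unmatched=True`` instead drops such lines (the behaviour
    of silently removing lines with missing measurements).
    """
    pheno_map = dict(zip(pheno.line_ids, pheno.values))
    shared = [lid for lid in expr.line_ids if lid in pheno_map]
    missing_e = [lid for lid in expr.line_ids if lid not in pheno_map]
    missing_p = [lid for lid in pheno.line_ids if lid not in set(expr.line_ids)]
    if (missing_e or missing_p) and not drop_unmatched:
        raise ValueError(
            f"unmatched lines: {len(missing_e)} expression-only, "
            f"{len(missing_p)} phenotype-only (pass drop_unmatched=True to drop)"
        )
    if missing_e or missing_p:
        logger.warning(
            "dropping %d unmatched lines", len(missing_e) + len(missing_p)
        )
    idx = np.array([expr.line_ids.index(lid) for lid in shared])
    return expr.subset_lines(idx), Phenotype(
        np.array([pheno_map[lid] for lid in shared]), shared
    )


# ---------------------------------------------------------------------------
# Transforms


def standardize(expr: ExpressionMatrix) -> StandardizedExpression:
    """Center each gene and scale to unit sample variance (denominator n-1).

    Constant (zero-variance) genes are excluded with a warning — CV subsets
    of real panels can produce them — rather than propagating NaNs. All-constant
    input is a hard error.
    """
    if expr.n_lines < 3:
        raise ValueError("standardize requires at least 3 lines")
    X = expr.values
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.any():
        raise ValueError("no variable genes")
    excluded = [g for g, k in zip(expr.gene_ids, keep) if not k]
    if excluded:
        logger.warning("excluding %d zero-variance genes", len(excluded))
    W = (X[:, keep] - means[keep]) / sds[keep]
    return StandardizedExpression(
        values=W,
        line_ids=expr.line_ids,
        gene_ids=[g for g, k in zip(expr.gene_ids, keep) if k],
        col_means=means[keep],
        col_sds=sds[keep],
        excluded_genes=excluded,
    )


def build_trm(W: StandardizedExpression | np.ndarray, scale_m: int | None = None) -> KernelMatrix:
    """Transcriptomic relationship matrix T = W W^T / m.

    With W fully standardized each gene contributes (n-1)/m to the trace, so
    trace(T) = n - 1 exactly. ``scale_m`` overrides the divisor (used for
    GO-partitioned kernels that divide by the total gene count).
    """
    V = W.values if isinstance(W, StandardizedExpression) else np.asarray(W, float)
    m = V.shape[1]
    if m == 0:
        raise ValueError("cannot build a kernel from 0 genes")
    divisor = m if scale_m is None else int(scale_m)
    T = V @ V.T / divisor
    T = (T + T.T) / 2.0  # exact symmetry against fp round-off
    return KernelMatrix(T, divisor)


def go_kernels(
    W: StandardizedExpression, members: list[str]
) -> tuple[KernelMatrix, KernelMatrix]:
    """Split the TRM into GO and not-GO components.

    Both kernels are divided by the *total* gene count m, so
    ``T_GO.values + T_notGO.values`` equals the full TRM exactly.
    """
    member_set = set(members)
    in_idx = [j for j, g in enumerate(W.gene_ids) if g in member_set]
    out_idx = [j for j, g in enumerate(W.gene_ids) if g not in member_set]
    if not in_idx:
        raise ValueError("empty GO block")
    if not out_idx:
        raise ValueError("GO term covers the whole universe; use a single kernel")
    m = W.n_genes
    return (
        build_trm(W.values[:, in_idx], scale_m=m),
        build_trm(W.values[:, out_idx], scale_m=m),
    )


def partition_genes(
    expr: ExpressionMatrix, members: list[str]
) -> tuple[ExpressionMatrix | None, ExpressionMatrix | None]:
    """Split columns into (in-set, out-of-set) blocks, preserving column order.

    The out-of-set block is ``None`` when the term covers the whole universe.
    """
    member_set = set(members)
    unknown = member_set - set(expr.gene_ids)
    if unknown:
        raise ValueError(f"{len(unknown)} term members outside the gene universe")
    in_genes = [g for g in expr.gene_ids if g in member_set]
    out_genes = [g for g in expr.gene_ids if g not in member_set]
    if not in_genes:
        raise ValueError("empty GO block")
    in_block = expr.subset_genes(in_genes)
    out_block = expr.subset_genes(out_genes) if out_genes else None
    return in_block, out_block


# ---------------------------------------------------------------------------
# Gene sets


def load_genesets(path, universe: list[str], min_size: int = 5) -> GeneSetCollection:
    """Read a GMT file, restrict membership to ``universe``, drop small sets.

    Sets with fewer than ``min_size`` members present in the universe are
    dropped (the >=5-genes-in-the-expression-data filter). Duplicate term IDs
    and malformed lines are hard errors.
    """
    universe_set = set(universe)
    sets: dict[str, list[str]] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 tab-separated fields")
            term = fields[0]
            if term in sets:
                raise ValueError(f"GMT line {lineno}: duplicate term ID {term!r}")
            members = list(dict.fromkeys(fields[2:]))  # dedupe, keep order
            present = [g for g in members if g in universe_set]
            if len(present) < min_size:
                n_dropped += 1
                logger.debug("dropping %s (%d members in universe)", term, len(present))
                continue
            sets[term] = present
    logger.info("retained %d gene sets (%d dropped below min_size=%d)",
                len(sets), n_dropped, min_size)
    return GeneSetCollection(sets, min_size=min_size)


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, columns=expr.gene_ids)
    df.insert(0, "line_id", expr.line_ids)
    df.to_csv(path, sep="\t", index=False)


def write_phenotype(pheno: Phenotype, path) -> None:
    pd.DataFrame({"line_id": pheno.line_ids, "value": pheno.values}).to_csv(
        path, sep="\t", index=False
    )


def write_genesets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, members in collection.sets.items():
            fh.write("\t".join([term, "synthetic"] + list(members)) + "\n")
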