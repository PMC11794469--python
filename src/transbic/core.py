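"""Core domain types: expression matrices, BTP-biclusters, and parameters.

A bucket trend-preserving (BTP) bicluster is a submatrix whose conditions
partition into an ordered sequence of *buckets* ``P1..Pl`` such that every
member gene's values are strictly ordered between consecutive buckets —
each gene either decreasing or increasing along the bucket order.  Within a
bucket a gene's values are unconstrained (ties allowed); across buckets the
inequalities are strict.

Partition orientation convention: buckets are stored in the order produced
by the extraction algorithm, so ``P1`` holds the *highest* expression for
genes labelled ``down`` and the lowest for genes labelled ``up``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "DOWN",
    "UP",
    "MatrixFormatError",
    "DimensionError",
    "ExpressionMatrix",
    "BTPBicluster",
    "TransBicParams",
    "BTPReport",
    "read_expression_matrix",
    "verify_btp",
    "write_biclusters",
    "read_biclusters",
]

#: Gene decreases along the stored bucket order (P1 = highest expression).
DOWN = "down"
#: Gene increases along the stored bucket order (P1 = lowest expression).
UP = "up"


class MatrixFormatError(ValueError):
    """Malformed expression-matrix input (duplicates, non-numeric cells...)."""


class DimensionError(ValueError):
    """Input dimensions outside the supported range."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """An n-gene by m-condition real-valued expression matrix.

    Parameters
    ----------
    values
        ``(n, m)`` float array; no missing values.
    gene_ids, condition_ids
        Unique row / column identifiers, order matching ``values``.
    """

    values: np.ndarray
    gene_ids: tuple
    condition_ids: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "condition_ids", tuple(self.condition_ids))
        if values.ndim != 2:
            raise DimensionError("expression values must be a 2-D array")
        n, m = values.shape
        if n < 2:
            raise DimensionError(f"need at least 2 genes, got {n}")
        if m < 3:
            raise DimensionError(f"need at least 3 conditions, got {m}")
        if len(self.gene_ids) != n or len(self.condition_ids) != m:
            raise MatrixFormatError("identifier count does not match matrix shape")
        if len(set(self.gene_ids)) != n:
            raise MatrixFormatError("duplicate gene identifiers")
        if len(set(self.condition_ids)) != m:
            raise MatrixFormatError("duplicate condition identifiers")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise MatrixFormatError(
                f"non-finite value for gene {self.gene_ids[bad[0]]!r} "
                f"under condition {self.condition_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def zscore_rows(self) -> "ExpressionMatrix":
        """Return a copy with each row standardized to mean 0, sd 1."""
        v = self.values
        sd = v.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        return ExpressionMatrix(
            (v - v.mean(axis=1, keepdims=True)) / sd,
            self.gene_ids,
            self.condition_ids,
        )


@dataclass(frozen=True)
class BTPBicluster:
    """A BTP-bicluster: member genes, per-gene direction, ordered buckets.

    ``partition`` is the ordered bucket sequence ``P1..Pl`` (tuples of
    condition indices); ``directions`` maps each member gene index to
    :data:`DOWN` or :data:`UP`; ``support`` counts member digraphs and
    ``p_value`` is the significance of the underlying common subdigraph.
    """

    gene_members: frozenset
    directions: Mapping[int, str]
    partition: tuple
    p_value: float = 1.0
    support: int = 0

    def __post_init__(self):
        object.__setattr__(self, "gene_members", frozenset(self.gene_members))
        part = tuple(tuple(sorted(p)) for p in self.partition)
        object.__setattr__(self, "partition", part)
        object.__setattr__(self, "directions", dict(self.directions))
        if len(part) < 2:
            raise ValueError("a BTP partition needs at least 2 buckets")
        if any(len(p) == 0 for p in part):
            raise ValueError("empty bucket in partition")
        flat = [c for p in part for c in p]
        if len(flat) != len(set(flat)):
            raise ValueError("partition buckets are not disjoint")
        if len(flat) < 2:
            raise ValueError("partition must cover at least 2 conditions")
        if len(self.gene_members) < 2:
            raise ValueError("a bicluster needs at least 2 genes")
        if set(self.directions) != set(self.gene_members):
            raise ValueError("every member gene needs exactly one direction")
        if any(d not in (DOWN, UP) for d in self.directions.values()):
            raise ValueError("directions must be 'down' or 'up'")

    @property
    def columns(self) -> tuple:
        """All condition indices, in bucket order."""
        return tuple(c for p in self.partition for c in p)

    def cells(self) -> set:
        """The (gene, condition) cell set spanned by the bicluster."""
        cols = self.columns
        return {(g, c) for g in self.gene_members for c in cols}


@dataclass
class TransBicParams:
    """Tunable thresholds of the biclustering pipeline.

    kl_threshold
        Minimum Kullback-Leibler admission score for growing the seed set
        (paper default 0.3).
    gamma_threshold
        Neighborhood-correlation cutoff for co-assigning conditions to one
        bucket (default 0.85).
    sigma_threshold
        Fraction of already-assigned conditions a candidate bucket seed
        must dominate (default 0.75).
    error_rate
        Tolerated fraction of missing arcs when testing whether a gene's
        digraph contains a common subdigraph (default 0.1).
    p_threshold
        Significance cutoff for accepting a bicluster (default 0.01).
    stabilization_iters
        Consecutive iterations the high-frequency arc set must stay
        unchanged before seed growth stops (default 2).
    min_genes
        Minimum member count of a reported bicluster (default 2).
    """

    kl_threshold: float = 0.3
    gamma_threshold: float = 0.85
    sigma_threshold: float = 0.75
    error_rate: float = 0.1
    p_threshold: float = 0.01
    stabilization_iters: int = 2
    min_genes: int = 2
    random_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma_threshold <= 1.0:
            raise ValueError("gamma_threshold must be in [0, 1]")
        if not 0.0 <= self.sigma_threshold <= 1.0:
            raise ValueError("sigma_threshold must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0.0 <= self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in [0, 1]")
        if self.stabilization_iters < 1:
            raise ValueError("stabilization_iters must be >= 1")
        if self.min_genes < 2:
            raise ValueError("min_genes must be >= 2")


def read_expression_matrix(path) -> ExpressionMatrix:
    """Load a tab-separated expression matrix.

    The first row holds condition names, the first column gene names.
    Rows with missing or non-numeric entries are rejected with an error
    naming the offending gene and condition.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if df.shape[1] < 3:
        raise DimensionError(
            f"need at least 3 condition columns, got {df.shape[1]}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise MatrixFormatError(f"duplicate gene identifier {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise MatrixFormatError(f"duplicate condition identifier {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        gi, ci = np.argwhere(numeric.isna().to_numpy())[0]
        raise MatrixFormatError(
            f"non-numeric value for gene {df.index[gi]!r} "
            f"under condition {df.columns[ci]!r}"
        )
    return ExpressionMatrix(
        numeric.to_numpy(dtype=float),
        tuple(str(g) for g in df.index),
        tuple(str(c) for c in df.columns),
    )


@dataclass(frozen=True)
class BTPReport:
    """Outcome of :func:`verify_btp`: a pass flag plus every violation."""

    ok: bool
    violations: tuple = ()


def verify_btp(matrix: ExpressionMatrix, bicluster: BTPBicluster) -> BTPReport:
    """Check the strict between-bucket inequalities of a BTP-bicluster.

    A gene labelled :data:`DOWN` must satisfy
    ``min(values over P_d) > max(values over P_{d+1})`` for every
    consecutive bucket pair; an :data:`UP` gene the reversed inequalities.
    Returns every violating ``(gene, d)`` pair (1-based ``d``).
    """
    m = matrix.n_conditions
    n = matrix.n_genes
    for bucket in bicluster.partition:
        for c in bucket:
            if not 0 <= c < m:
                raise IndexError(f"condition index {c} out of range")
    violations = []
    for g in sorted(bicluster.gene_members):
        if not 0 <= g < n:
            raise IndexError(f"gene index {g} out of range")
        row = matrix.values[g]
        direction = bicluster.directions[g]
        for d in range(len(bicluster.partition) - 1):
            cur = row[list(bicluster.partition[d])]
            nxt = row[list(bicluster.partition[d + 1])]
            if direction == DOWN:
                ok = cur.min() > nxt.max()
            else:
                ok = cur.max() < nxt.min()
            if not ok:
                violations.append((g, d + 1))
    return BTPReport(ok=not violations, violations=tuple(violations))


def write_biclusters(
    out: TextIO,
    biclusters: Sequence[BTPBicluster],
    gene_ids: Sequence[str],
    condition_ids: Sequence[str],
) -> None:
    """Write biclusters as plain text blocks.

    Each block: ``#bicluster k p=<p>``, a ``buckets:`` line with
    pipe-separated buckets of comma-separated condition names (stored
    order, i.e. decreasing expression for ``down`` genes), then one
    ``<gene>\\t<down|up>`` line per member gene.
    """
    for k, b in enumerate(biclusters):
        out.write(f"#bicluster {k} p={b.p_value:.6g}\n")
        buckets = "|".join(
            "{" + ",".join(condition_ids[c] for c in p) + "}" for p in b.partition
        )
        out.write(f"buckets: {buckets}\n")
        for g in sorted(b.gene_members):
            out.write(f"{gene_ids[g]}\t{b.directions[g]}\n")


def read_biclusters(
    lines: Iterable[str],
    gene_ids: Sequence[str],
    condition_ids: Sequence[str],
) -> list:
    """Parse the text format written by :func:`write_biclusters`."""
    gidx = {g: i for i, g in enumerate(gene_ids)}
    cidx = {c: i for i, c in enumerate(condition_ids)}
    result = []
    header = None
    partition = None
    members = {}

    def flush():
        if header is not None and members:
            result.append(
                BTPBicluster(
                    gene_members=frozenset(members),
                    directions=dict(members),
                    partition=partition,
                    p_value=header,
                    support=len(members),
                )
            )

    for raw in lines:
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("#bicluster"):
            flush()
            header = float(line.split("p=")[1])
            partition, members = None, {}
        elif line.startswith("buckets:"):
            spec = line.split(":", 1)[1].strip()
            partition = tuple(
                tuple(cidx[c] for c in chunk.strip("{}").split(",") if c)
                for chunk in spec.split("|")
            )
        elif not line.startswith("#"):
            name, direction = line.split("\t")
            members[gidx[name]] = direction
    flush()
    return result
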