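"""Synthetic expression benchmarks with implanted local patterns.

Backgrounds are either per-entry Gaussian ``N(1, 1)`` or, in ``mixed``
mode, per-row draws from one of five families (Normal, Gamma, Bimodal,
Cauchy, Lognormal) followed by per-row z-scoring.  Biclusters are
implanted distribution-preservingly where possible: the affected values
of each row are *reordered* (not resampled) so the target pattern holds,
leaving every row's value multiset unchanged.  Parametric patterns
(column-constant, shifting, scaling, shifting-scaling, checkerboard)
resample from the background family with parameters drawn from fixed
printed sets.

Noise replaces in-bicluster values with fresh background draws until the
*basic-unit* deviation of each row — the fraction of within-bicluster
condition pairs whose order contradicts the intended pattern — comes as
close to a target level as the pair granularity allows without exceeding
it.  The bicluster's noise level is the maximum over its rows.
Fluctuations add i.i.d. ``N(0, sigma)`` to every entry of the matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .core import DOWN, UP, ExpressionMatrix

__all__ = [
    "SHIFT_SET",
    "SCALE_SET",
    "PATTERNS",
    "PRESETS",
    "GroundTruthBicluster",
    "GroundTruth",
    "generate_background",
    "implant_bicluster",
    "add_noise",
    "noise_level_of",
    "add_fluctuations",
    "simulate",
    "save_truth",
    "load_truth",
]

SHIFT_SET = (-1.0, -0.8, -0.5, -0.2, 0.0, 0.2, 0.5, 0.8, 1.0)
SCALE_SET = (-3.0, -2.0, -1.0, 1.0, 2.0, 3.0)

PATTERNS = (
    "column_constant",
    "shifting",
    "scaling",
    "shifting_scaling",
    "order_preserving",
    "trend_preserving",
    "btp",
    "checkerboard",
)

_FAMILIES = ("normal", "gamma", "bimodal", "cauchy", "lognormal")


@dataclass(frozen=True)
class GroundTruthBicluster:
    """One implanted bicluster: location, pattern, and its BTP reading.

    ``partition`` (ordered buckets of absolute column indices, highest
    expression first for ``down`` rows) and ``directions`` are None only
    for patterns with no bucket representation (checkerboard).
    """

    rows: tuple
    cols: tuple
    pattern: str
    partition: Optional[tuple] = None
    directions: Optional[dict] = None

    def cells(self) -> frozenset:
        return frozenset((r, c) for r in self.rows for c in self.cols)


@dataclass
class GroundTruth:
    """All implanted biclusters of one simulated matrix."""

    n: int
    m: int
    background: str = "gaussian"
    biclusters: list = field(default_factory=list)


def _sample_family(rng: np.random.Generator, family: str, size: int) -> np.ndarray:
    if family == "normal":
        return rng.normal(0.0, 1.0, size)
    if family == "gamma":
        return rng.gamma(2.0, 1.0, size)
    if family == "bimodal":  # equal mixture of N(-2,1) and N(2,1)
        comp = rng.integers(0, 2, size)
        return rng.normal(0.0, 1.0, size) + np.where(comp == 0, -2.0, 2.0)
    if family == "cauchy":
        return rng.standard_cauchy(size)
    if family == "lognormal":
        return rng.lognormal(0.0, 1.0, size)
    raise ValueError(f"unknown family {family!r}")


def generate_background(
    n: int, m: int, mode: str = "gaussian", seed: int = 0
) -> ExpressionMatrix:
    """Background matrix with no implanted structure.

    ``gaussian``: every entry ``N(1, 1)``.  ``mixed``: each row drawn
    from one of five distribution families chosen uniformly, then
    z-scored.  Bit-reproducible for a fixed seed.
    """
    if n < 2 or m < 3:
        raise ValueError("background needs n >= 2 and m >= 3")
    rng = np.random.default_rng(seed)
    if mode == "gaussian":
        values = rng.normal(1.0, 1.0, (n, m))
    elif mode == "mixed":
        values = np.empty((n, m))
        for i in range(n):
            family = _FAMILIES[rng.integers(0, len(_FAMILIES))]
            row = _sample_family(rng, family, m)
            sd = row.std(ddof=0)
            values[i] = (row - row.mean()) / (sd if sd > 0 else 1.0)
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    gene_ids = tuple(f"g{i+1}" for i in range(n))
    condition_ids = tuple(f"c{j+1}" for j in range(m))
    return ExpressionMatrix(values, gene_ids, condition_ids)


def _split_buckets(
    cols: Sequence[int], n_buckets: int, rng: np.random.Generator
) -> tuple:
    """Random partition of ``cols`` into ``n_buckets`` near-equal buckets."""
    cols = list(cols)
    if not 2 <= n_buckets <= len(cols):
        raise ValueError("bucket count must be between 2 and |cols|")
    shuffled = [cols[i] for i in rng.permutation(len(cols))]
    base, extra = divmod(len(cols), n_buckets)
    sizes = [base + (1 if b < extra else 0) for b in range(n_buckets)]
    buckets, start = [], 0
    for s in sizes:
        buckets.append(tuple(shuffled[start : start + s]))
        start += s
    return tuple(buckets)


def _default_directions(rows: Sequence[int]) -> dict:
    """Half the rows decrease along the bucket order, half increase."""
    rows = sorted(rows)
    half = (len(rows) + 1) // 2
    return {r: (DOWN if i < half else UP) for i, r in enumerate(rows)}


def _reorder_row_to_partition(
    values: np.ndarray,
    partition: Sequence[Sequence[int]],
    direction: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reassign a row's own values so the bucket inequalities hold.

    ``down``: the largest values go to the first bucket.  Within a bucket
    the placement is random, so same-bucket pair orders stay arbitrary.
    Returns the full-length row copy with in-bicluster entries rewritten.
    """
    cols = [c for p in partition for c in p]
    pool = np.sort(values[cols])
    if direction == DOWN:
        pool = pool[::-1]
    out = values.copy()
    start = 0
    for bucket in partition:
        chunk = pool[start : start + len(bucket)]
        order = rng.permutation(len(bucket))
        for pos, c in enumerate(bucket):
            out[c] = chunk[order[pos]]
        start += len(bucket)
    return out


def implant_bicluster(
    matrix: ExpressionMatrix,
    rows: Sequence[int],
    cols: Sequence[int],
    pattern: str,
    pattern_params: Optional[dict] = None,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
):
    """Implant one patterned bicluster; returns ``(matrix, truth entry)``.

    Reorder-based patterns (``btp``, ``order_preserving``,
    ``trend_preserving``) keep each row's value multiset unchanged.
    Parametric patterns draw shifting offsets from :data:`SHIFT_SET` and
    scaling factors from :data:`SCALE_SET` applied to a fresh ``N(1, 1)``
    base profile.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    params = dict(pattern_params or {})
    rows = sorted(int(r) for r in rows)
    cols = sorted(int(c) for c in cols)
    if max(rows) >= matrix.n_genes or max(cols) >= matrix.n_conditions:
        raise IndexError("bicluster indices out of matrix bounds")
    values = matrix.values.copy()

    partition: Optional[tuple] = None
    directions: Optional[dict] = None

    if pattern == "btp":
        partition = params.get("partition")
        if partition is None:
            partition = _split_buckets(cols, params.get("n_buckets", 4), rng)
        else:
            partition = tuple(tuple(int(c) for c in p) for p in partition)
        directions = params.get("directions") or _default_directions(rows)
        for r in rows:
            values[r] = _reorder_row_to_partition(
                values[r], partition, directions[r], rng
            )
    elif pattern in ("order_preserving", "trend_preserving"):
        perm = [cols[i] for i in rng.permutation(len(cols))]
        partition = tuple((c,) for c in perm)
        if pattern == "order_preserving":
            directions = {r: DOWN for r in rows}
        else:
            directions = _default_directions(rows)
        for r in rows:
            values[r] = _reorder_row_to_partition(
                values[r], partition, directions[r], rng
            )
    elif pattern in ("column_constant", "shifting", "scaling", "shifting_scaling"):
        base = rng.normal(1.0, 1.0, len(cols))
        while len(np.unique(base)) < len(base):  # pragma: no cover
            base = rng.normal(1.0, 1.0, len(cols))
        scales = np.ones(len(rows))
        shifts = np.zeros(len(rows))
        if pattern in ("scaling", "shifting_scaling"):
            scales = rng.choice(SCALE_SET, len(rows))
        if pattern in ("shifting", "shifting_scaling"):
            shifts = rng.choice(SHIFT_SET, len(rows))
        for a, b, r in zip(scales, shifts, rows):
            values[r, cols] = a * base + b
        # common bucket reading: singleton buckets along descending base
        order = np.argsort(-base)
        partition = tuple((cols[i],) for i in order)
        directions = {
            r: (DOWN if a > 0 else UP) for a, r in zip(scales, rows)
        }
    elif pattern == "checkerboard":
        n_row_blocks = params.get("n_row_blocks", 2)
        n_col_blocks = params.get("n_col_blocks", 2)
        row_blocks = np.array_split(np.array(rows), n_row_blocks)
        col_blocks = np.array_split(np.array(cols), n_col_blocks)
        for rb in row_blocks:
            for cb in col_blocks:
                values[np.ix_(rb, cb)] = rng.normal(1.0, 1.0)

    out = ExpressionMatrix(values, matrix.gene_ids, matrix.condition_ids)
    entry = GroundTruthBicluster(
        rows=tuple(rows),
        cols=tuple(cols),
        pattern=pattern,
        partition=partition,
        directions=directions,
    )
    return out, entry


def _row_deviation(
    row: np.ndarray, entry: GroundTruthBicluster, r: int
) -> float:
    """Fraction of within-bicluster condition pairs violating the pattern."""
    k = len(entry.cols)
    n_pairs = k * (k - 1) // 2
    bucket_of = {}
    for d, bucket in enumerate(entry.partition):
        for c in bucket:
            bucket_of[c] = d
    direction = entry.directions[r]
    bad = 0
    for c1, c2 in combinations(entry.cols, 2):
        d1, d2 = bucket_of[c1], bucket_of[c2]
        if d1 == d2:
            continue  # same bucket: no expected order
        hi, lo = (c1, c2) if d1 < d2 else (c2, c1)
        if direction == UP:
            hi, lo = lo, hi
        if not row[hi] > row[lo]:
            bad += 1
    return bad / n_pairs


def noise_level_of(matrix: ExpressionMatrix, truth: GroundTruth) -> list:
    """Per-bicluster noise level: max basic-unit deviation over rows.

    Entries without a bucket representation yield None.
    """
    levels = []
    for entry in truth.biclusters:
        if entry.partition is None:
            levels.append(None)
            continue
        levels.append(
            max(
                _row_deviation(matrix.values[r], entry, r)
                for r in entry.rows
            )
        )
    return levels


def add_noise(
    matrix: ExpressionMatrix,
    truth: GroundTruth,
    target_level: float,
    seed: int = 0,
    max_attempts: int = 400,
) -> ExpressionMatrix:
    """Push every bicluster row's deviation toward ``target_level``.

    Values inside each bicluster are replaced one at a time with fresh
    background draws; a replacement is kept only when it increases the
    row's deviation without exceeding the target, so the final level sits
    just below the target within pair granularity.  ``target_level = 0``
    returns the matrix unchanged.
    """
    if not 0.0 <= target_level <= 1.0:
        raise ValueError("target_level must be in [0, 1]")
    if target_level == 0.0:
        return matrix
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()

    def draw():
        if truth.background == "gaussian":
            return rng.normal(1.0, 1.0)
        return rng.normal(0.0, 1.0)  # mixed rows are z-scored

    for entry in truth.biclusters:
        if entry.partition is None:
            continue
        for r in entry.rows:
            cur = _row_deviation(values[r], entry, r)
            for _ in range(max_attempts):
                if cur >= target_level:
                    break
                c = entry.cols[rng.integers(0, len(entry.cols))]
                old = values[r, c]
                values[r, c] = draw()
                new = _row_deviation(values[r], entry, r)
                if cur < new <= target_level:
                    cur = new
                else:
                    values[r, c] = old
    return ExpressionMatrix(values, matrix.gene_ids, matrix.condition_ids)


def add_fluctuations(
    matrix: ExpressionMatrix, sigma: float, seed: int = 0
) -> ExpressionMatrix:
    """Add i.i.d. ``N(0, sigma)`` to every entry (identity for sigma=0)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        return matrix
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        matrix.values + rng.normal(0.0, sigma, matrix.values.shape),
        matrix.gene_ids,
        matrix.condition_ids,
    )


#: Named scenario configurations (background plus implants).
PRESETS = {
    "mini-single": {
        "n": 40,
        "m": 15,
        "mode": "gaussian",
        "implants": [
            {"rows": 10, "cols": 8, "pattern": "btp", "n_buckets": 3}
        ],
    },
    "clean-single": {
        "n": 100,
        "m": 30,
        "mode": "gaussian",
        "implants": [
            {"rows": 20, "cols": 10, "pattern": "btp", "n_buckets": 4}
        ],
    },
    "two-disjoint": {
        "n": 100,
        "m": 30,
        "mode": "gaussian",
        "implants": [
            {"rows": 20, "cols": 10, "pattern": "btp", "n_buckets": 4},
            {"rows": 20, "cols": 10, "pattern": "btp", "n_buckets": 4},
        ],
    },
    "overlap-pair": {
        "n": 100,
        "m": 30,
        "mode": "gaussian",
        "implants": [
            {"rows": 20, "cols": 10, "pattern": "btp", "n_buckets": 4},
            {
                "rows": 20,
                "cols": 10,
                "pattern": "btp",
                "n_buckets": 4,
                "row_overlap": 10,
            },
        ],
    },
    "background-only": {"n": 100, "m": 30, "mode": "gaussian", "implants": []},
    "mixed-background": {
        "n": 200,
        "m": 50,
        "mode": "mixed",
        "implants": [
            {"rows": 20, "cols": 12, "pattern": "btp", "n_buckets": 4}
        ],
    },
}


def simulate(
    preset: str,
    seed: int = 0,
    noise_level: float = 0.0,
    fluctuation_sigma: float = 0.0,
):
    """Generate a preset scenario; returns ``(matrix, truth)``.

    Implant locations are drawn from disjoint row/column pools unless an
    implant requests ``row_overlap`` shared genes with the previous one.
    Noise (if any) is injected before fluctuations, matching the
    benchmark construction order.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    rng = np.random.default_rng(seed)
    matrix = generate_background(
        cfg["n"], cfg["m"], cfg["mode"], seed=int(rng.integers(2**31))
    )
    truth = GroundTruth(n=cfg["n"], m=cfg["m"], background=cfg["mode"])
    free_rows = list(range(cfg["n"]))
    free_cols = list(range(cfg["m"]))
    prev_rows: list = []
    for spec in cfg["implants"]:
        overlap = int(spec.get("row_overlap", 0))
        take_new = spec["rows"] - overlap
        shared = list(prev_rows[:overlap])
        rows = shared + [
            free_rows[i]
            for i in rng.choice(len(free_rows), take_new, replace=False)
        ]
        cols = [
            free_cols[i]
            for i in rng.choice(len(free_cols), spec["cols"], replace=False)
        ]
        matrix, entry = implant_bicluster(
            matrix,
            rows,
            cols,
            spec["pattern"],
            {"n_buckets": spec.get("n_buckets", 4)},
            rng=rng,
        )
        truth.biclusters.append(entry)
        free_rows = [r for r in free_rows if r not in set(rows)]
        free_cols = [c for c in free_cols if c not in set(cols)]
        prev_rows = rows
    if noise_level > 0:
        matrix = add_noise(
            matrix, truth, noise_level, seed=int(rng.integers(2**31))
        )
    if fluctuation_sigma > 0:
        matrix = add_fluctuations(
            matrix, fluctuation_sigma, seed=int(rng.integers(2**31))
        )
    return matrix, truth


def save_truth(path, truth: GroundTruth, matrix: ExpressionMatrix) -> None:
    """Serialize ground truth (with identifier lists) as JSON."""
    doc = {
        "n": truth.n,
        "m": truth.m,
        "background": truth.background,
        "gene_ids": list(matrix.gene_ids),
        "condition_ids": list(matrix.condition_ids),
        "biclusters": [
            {
                "rows": list(b.rows),
                "cols": list(b.cols),
                "pattern": b.pattern,
                "partition": (
                    [list(p) for p in b.partition]
                    if b.partition is not None
                    else None
                ),
                "directions": (
                    {str(r): d for r, d in b.directions.items()}
                    if b.directions is not None
                    else None
                ),
            }
            for b in truth.biclusters
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_truth(path):
    """Load ground truth saved by :func:`save_truth`.

    Returns ``(truth, gene_ids, condition_ids)``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    truth = GroundTruth(
        n=doc["n"], m=doc["m"], background=doc.get("background", "gaussian")
    )
    for b in doc["biclusters"]:
        truth.biclusters.append(
            GroundTruthBicluster(
                rows=tuple(b["rows"]),
                cols=tuple(b["cols"]),
                pattern=b["pattern"],
                partition=(
                    tuple(tuple(p) for p in b["partition"])
                    if b["partition"] is not None
                    else None
                ),
                directions=(
                    {int(r): d for r, d in b["directions"].items()}
                    if b["directions"] is not None
                    else None
                ),
            )
        )
    return truth, tuple(doc["gene_ids"]), tuple(doc["condition_ids"])
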