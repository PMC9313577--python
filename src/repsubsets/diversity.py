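"""Simpson diversity/clonality and Jaccard overlap, with subsample-to-smallest
resampling normalization.

Simpson's diversity index

    D = Σᵢ nᵢ(nᵢ−1) / (N(N−1))

is the probability that two cells drawn without replacement from the sample
belong to the same clone (nᵢ = template count of clone i, N = Σ nᵢ).
Simpson's clonality is √D: 0 for a fully polyclonal (all-singleton) sample,
1 for a monoclonal one.  The Jaccard index |A∩B| / |A∪B| measures clonotype
sharing on unique key sets, abundance ignored.

Because both statistics depend on sampling depth, repertoires in a comparison
are normalized by subsampling the larger ones — uniformly, without
replacement, at the level of *unique clonotypes* (template counts retained) —
down to the number of unique clonotypes in the smallest repertoire, and the
statistic is averaged over many subsampling iterations (100 000 by default).
The smallest repertoire is used as-is.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SizeError, UndefinedStatisticError, ValidationError
from .records import Frame, RepLabel, Repertoire
from .repertoire_io import partition_by_frame

#: the study's default number of subsampling iterations
DEFAULT_N_ITER = 100_000


# ---------------------------------------------------------------------------
# point statistics
# ---------------------------------------------------------------------------

def _validated_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.size == 0:
        raise UndefinedStatisticError("empty count vector")
    if not np.issubdtype(c.dtype, np.integer):
        if not np.all(c == np.floor(c)):
            raise ValidationError("clone counts must be integers")
        c = c.astype(np.int64)
    if np.any(c < 1):
        raise ValidationError("clone counts must all be >= 1")
    return c.astype(np.int64)


def simpson_diversity(counts) -> float:
    """Simpson's diversity D = Σ nᵢ(nᵢ−1) / (N(N−1)) for clone counts nᵢ.

    Requires every count >= 1 and N = Σ nᵢ >= 2 (two cells are needed to
    draw a pair).
    """
    c = _validated_counts(counts)
    n_total = int(c.sum())
    if n_total < 2:
        raise UndefinedStatisticError(
            f"Simpson's diversity undefined for N={n_total} < 2")
    same = int((c * (c - 1)).sum())
    return same / (n_total * (n_total - 1))


def simpson_clonality(counts) -> float:
    """Simpson's clonality √D; 0 = fully polyclonal, 1 = monoclonal."""
    return math.sqrt(simpson_diversity(counts))


def jaccard_index(set_a, set_b) -> float:
    """|A∩B| / |A∪B| on two non-empty clonotype key sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise UndefinedStatisticError("Jaccard index undefined for empty sets")
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# seeded substreams
# ---------------------------------------------------------------------------

def _stream(seed: int, operation: str, label: RepLabel, dup: int = 0) -> np.random.Generator:
    """Deterministic per-(operation, repertoire-label) random stream.

    Each repertoire's subsampling stream depends only on the master seed,
    the operation name, and its own label — never on the order in which
    repertoires are passed — so pairwise results are symmetric and a run is
    reproducible regardless of evaluation order.  ``dup`` disambiguates the
    two sides when a repertoire is compared against itself.
    """
    digest = hashlib.sha256(
        f"{operation}|{label}|{dup}".encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    ss = np.random.SeedSequence([int(seed) & 0xFFFFFFFF, *map(int, words)])
    return np.random.default_rng(ss)


def _draw_indices(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct indices from range(n), uniform over k-subsets."""
    return rng.choice(n, size=k, replace=False, shuffle=False)


# ---------------------------------------------------------------------------
# subsampling and resampled statistics
# ---------------------------------------------------------------------------

def subsample_unique(rep: Repertoire, k: int, rng_state) -> Repertoire:
    """Draw ``k`` unique clonotypes from ``rep`` uniformly without
    replacement, retaining their template counts.

    ``rng_state`` may be a ``numpy.random.Generator`` or an integer seed.
    ``k = R`` returns a repertoire equal to the input (up to record order).
    """
    if k < 1:
        raise ValidationError(f"subsample size must be >= 1, got {k}")
    if k > rep.R:
        raise SizeError(
            f"cannot draw k={k} unique clonotypes from repertoire "
            f"{rep.label} with R={rep.R}")
    rng = (rng_state if isinstance(rng_state, np.random.Generator)
           else np.random.default_rng(rng_state))
    if k == rep.R:
        return rep
    return rep.subset_by_indices(_draw_indices(rng, rep.R, k))


@dataclass(frozen=True)
class DiversityResult:
    """A (possibly resampling-normalized) clonality/diversity estimate with
    full provenance: subsample size ``k``, iteration count, seed, and the
    spread of the subsampled statistic."""

    statistic: str                  # "simpson_D" or "simpson_clonality"
    point_value: float              # full-sample value
    source_label: RepLabel
    k: int
    n_iter: int
    seed: int
    resampled_mean: float | None = None
    resampled_sd: float | None = None


def resampled_clonality(
    rep: Repertoire, k: int, n_iter: int = DEFAULT_N_ITER, seed: int = 0,
    statistic: str = "simpson_clonality",
) -> DiversityResult:
    """Average Simpson's clonality over ``n_iter`` subsamples of ``k``
    unique clonotypes.

    Deterministic given ``seed``.  ``k = R`` reproduces the point value with
    zero spread (the smallest repertoire in a comparison is used as-is).
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if statistic not in ("simpson_clonality", "simpson_D"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    stat = simpson_clonality if statistic == "simpson_clonality" else simpson_diversity
    counts = rep.counts()
    point = stat(counts)
    if k == rep.R:
        return DiversityResult(statistic, point, rep.label, k, n_iter, seed,
                               resampled_mean=point, resampled_sd=0.0)
    if k > rep.R:
        raise SizeError(f"k={k} exceeds R={rep.R} of repertoire {rep.label}")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    rng = _stream(seed, "resampled_clonality", rep.label)
    vals = np.empty(n_iter)
    for i in range(n_iter):
        idx = _draw_indices(rng, rep.R, k)
        vals[i] = stat(counts[idx])
    return DiversityResult(
        statistic, point, rep.label, k, n_iter, seed,
        resampled_mean=float(vals.mean()), resampled_sd=float(vals.std()))


@dataclass(frozen=True)
class OverlapResult:
    """Resampling-normalized Jaccard overlap between two repertoires."""

    labels: tuple[RepLabel, RepLabel]
    jaccard_mean: float
    jaccard_sd: float
    k: int
    n_iter: int
    seed: int
    n_shared_full: int              # intersection size without subsampling


def resampled_jaccard(
    rep_a: Repertoire, rep_b: Repertoire, k: int,
    n_iter: int = DEFAULT_N_ITER, seed: int = 0,
) -> OverlapResult:
    """Average Jaccard index over ``n_iter`` iterations, each subsampling
    both repertoires independently to ``k`` unique clonotypes (a repertoire
    with R = k is used as-is).

    Symmetric under swapping the inputs: each repertoire's subsampling
    stream is derived from its own label, not from argument position.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    for rep in (rep_a, rep_b):
        if k > rep.R:
            raise SizeError(
                f"k={k} exceeds R={rep.R} of repertoire {rep.label}")
        if rep.R == 0:
            raise UndefinedStatisticError(
                f"repertoire {rep.label} is empty")

    keys_a, keys_b = rep_a.keys(), rep_b.keys()
    id_of: dict[tuple, int] = {}
    for key in keys_a + keys_b:
        id_of.setdefault(key, len(id_of))
    ids_a = np.array([id_of[key] for key in keys_a], dtype=np.int64)
    ids_b = np.array([id_of[key] for key in keys_b], dtype=np.int64)
    n_shared_full = int(np.intersect1d(ids_a, ids_b).size)

    same_label = rep_a.label == rep_b.label
    rng_a = _stream(seed, "resampled_jaccard", rep_a.label, dup=0)
    rng_b = _stream(seed, "resampled_jaccard", rep_b.label,
                    dup=1 if same_label else 0)

    jac = np.empty(n_iter)
    for i in range(n_iter):
        sa = ids_a if k == rep_a.R else ids_a[_draw_indices(rng_a, rep_a.R, k)]
        sb = ids_b if k == rep_b.R else ids_b[_draw_indices(rng_b, rep_b.R, k)]
        inter = np.intersect1d(sa, sb).size
        jac[i] = inter / (2 * k - inter)
    return OverlapResult(
        labels=(rep_a.label, rep_b.label),
        jaccard_mean=float(jac.mean()), jaccard_sd=float(jac.std()),
        k=k, n_iter=n_iter, seed=seed, n_shared_full=n_shared_full)


def pairwise_overlap_matrix(
    reps: Sequence[Repertoire], n_iter: int = DEFAULT_N_ITER, seed: int = 0,
    frame: str | Frame | None = Frame.productive,
) -> pd.DataFrame:
    """Symmetric matrix of :class:`OverlapResult` over all repertoire pairs.

    Each repertoire is first restricted to the requested frame (``None``
    keeps all records); repertoires left empty are excluded with a warning.
    The common subsample size k is the smallest R among the remaining
    repertoires.  Diagonal cells are exact self-overlaps (Jaccard 1).

    Returns an object-dtype DataFrame indexed by repertoire label strings;
    use :func:`overlap_means` for the numeric matrix.
    """
    filtered = []
    for rep in reps:
        if frame is not None:
            f = Frame(frame)
            prod, nonprod = partition_by_frame(rep)
            rep = prod if f is Frame.productive else nonprod
        if rep.R < 1:
            warnings.warn(
                f"repertoire {rep.label} has no clonotypes in the requested "
                "frame; excluded from the overlap matrix", stacklevel=2)
            continue
        filtered.append(rep)
    if len(filtered) < 2:
        raise ValidationError(
            "need at least 2 non-empty repertoires for an overlap matrix")
    k = min(rep.R for rep in filtered)
    names = [str(rep.label) for rep in filtered]
    mat = pd.DataFrame(index=names, columns=names, dtype=object)
    for i, ra in enumerate(filtered):
        mat.iloc[i, i] = OverlapResult(
            labels=(ra.label, ra.label), jaccard_mean=1.0, jaccard_sd=0.0,
            k=ra.R, n_iter=1, seed=seed, n_shared_full=ra.R)
        for j in range(i + 1, len(filtered)):
            res = resampled_jaccard(ra, filtered[j], k=k,
                                    n_iter=n_iter, seed=seed)
            mat.iloc[i, j] = res
            mat.iloc[j, i] = res
    return mat


def overlap_means(matrix: pd.DataFrame) -> pd.DataFrame:
    """Numeric matrix of jaccard_mean values from a pairwise-overlap matrix."""
    return matrix.map(lambda r: r.jaccard_mean).astype(float)
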