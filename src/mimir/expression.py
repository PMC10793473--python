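"""Gene-by-pseudotime expression profiles and the scaled expression
similarity S_exp.

Each gene's profile is its per-segment mean log2-normalized expression along
the trajectory (the earliest, pre-specification segment can be excluded).
Pairwise profile distances (Jensen-Shannon divergence by default; Euclidean,
cosine and Canberra as alternatives) are scaled to [0, 0.95] preserving zero
— so identical dynamics always attain similarity 1 — and similarity is one
minus the scaled distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .enrichment import SegmentPartition
from .io import NormalizedMatrix

logger = logging.getLogger(__name__)

METRICS = ("jsd", "euclidean", "cosine", "canberra")


@dataclass
class PseudotimeProfile:
    gene_ids: list[str]
    bins: list[tuple[float, float]]
    values: np.ndarray  # genes x bins, mean log2 expression
    excluded_prefix: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.bins])


@dataclass
class SimilarityMatrix:
    """Symmetric gene-by-gene similarity. Diagonal is 1 for expression and
    functional kinds; the combined kind's diagonal follows its fusion rule."""

    gene_ids: list[str]
    values: np.ndarray
    kind: str  # expression | functional | combined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match gene list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


def build_profiles(
    data: NormalizedMatrix,
    segments: SegmentPartition,
    genes: list[str],
    exclude_presegment: bool = False,
) -> PseudotimeProfile:
    """Per-segment mean expression profile for each requested gene.

    Segment cells absent from ``data`` are ignored (the partition may have
    been built on a superset of cells). With ``exclude_presegment`` the
    earliest segment — cells not yet specified into the trajectory's fate —
    is dropped and recorded in ``excluded_prefix``.
    """
    missing = [g for g in genes if g not in set(data.gene_ids)]
    if missing:
        raise KeyError(f"genes absent from data: {missing[:10]}")
    pos = {c: i for i, c in enumerate(data.cell_ids)}
    gidx = {g: i for i, g in enumerate(data.gene_ids)}
    rows = [gidx[g] for g in genes]

    segs = segments.segments[1:] if exclude_presegment else segments.segments
    if not segs:
        raise ValueError("no segments remain after exclusion")
    values = np.zeros((len(genes), len(segs)))
    bins = []
    for bi, seg in enumerate(segs):
        cells = [pos[c] for c in seg.cell_ids if c in pos]
        if not cells:
            raise ValueError(f"segment {seg.interval} has no cells present in the data")
        values[:, bi] = data.values[np.ix_(rows, cells)].mean(axis=1)
        bins.append(seg.interval)
    return PseudotimeProfile(
        gene_ids=list(genes),
        bins=bins,
        values=values,
        excluded_prefix=1 if exclude_presegment else 0,
    )


def _jsd_matrix(profiles: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Pairwise Jensen-Shannon divergence (base-2 logs, bounded by 1) on
    sum-normalized profiles."""
    sums = profiles.sum(axis=1)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValueError(f"all-zero profiles under jsd: {[gene_ids[i] for i in zero[:10]]}")
    P = profiles / sums[:, None]

    def H(mat: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(mat > 0, mat * np.log2(mat), 0.0)
        return -term.sum(axis=-1)

    h = H(P)
    n = len(P)
    D = np.zeros((n, n))
    for i in range(n - 1):
        M = (P[i][None, :] + P[i + 1 :]) / 2.0
        jsd = H(M) - (h[i] + h[i + 1 :]) / 2.0
        D[i, i + 1 :] = D[i + 1 :, i] = np.clip(jsd, 0.0, 1.0)
    return D


def profile_distance(p: PseudotimeProfile, metric: str = "jsd") -> pd.DataFrame:
    """Symmetric gene-pair distance table (zero diagonal) under the chosen
    metric. jsd uses the divergence itself (not its square root)."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if metric == "jsd":
        D = _jsd_matrix(p.values, p.gene_ids)
    else:
        with np.errstate(invalid="ignore"):
            D = squareform(pdist(p.values, metric=metric))
        D = np.nan_to_num(D, nan=1.0)  # cosine distance of a zero profile
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=p.gene_ids, columns=p.gene_ids)


def expression_similarity(distances: pd.DataFrame, cap: float = 0.95, scaling: str = "max") -> SimilarityMatrix:
    """S_exp = 1 - d', where d' rescales the distances to span [0, ``cap``].

    The default scaling is zero-preserving (d' = cap * d / max d), so a pair
    with identical profiles keeps similarity exactly 1; ``scaling="minmax"``
    maps [min, max] onto [0, cap] instead, for comparison.
    """
    D = np.asarray(distances, dtype=float)
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    dmax = D.max()
    if dmax == 0:
        logger.warning("all distances zero; similarities are all 1")
        scaled = np.zeros_like(D)
    elif scaling == "max":
        scaled = cap * D / dmax
    elif scaling == "minmax":
        off = D[~np.eye(len(D), dtype=bool)]
        dmin = off.min()
        rng = dmax - dmin
        scaled = np.where(D == 0, 0.0, cap * (D - dmin) / rng) if rng > 0 else np.zeros_like(D)
    else:
        raise ValueError(f"scaling must be 'max' or 'minmax', got {scaling!r}")
    sim = 1.0 - scaled
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(gene_ids=list(distances.index), values=sim, kind="expression")
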