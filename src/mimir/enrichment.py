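"""Trajectory-enriched gene identification.

The pseudotime line is divided into equal segments (default 15), segments
with too few cells (default < 60) are fused with neighbours so the final
counts are as even as possible, and each gene is scored per segment as a
classifier of trajectory vs background cells using the area under the
precision-recall curve (AUCPR). A gene passes in a window when it is detected
in at least 10% of the group cells, its AUCPR is at least ``fold`` times the
uninformative expectation, and its log fold change exceeds 0.3. Trajectory
mode admits genes passing in the final segment or in at least two segments;
stage mode admits genes passing in any stage window. Term over-representation
uses the one-sided Fisher exact (hypergeometric tail) test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import average_precision_score

from .io import AnnotationMap, NormalizedMatrix

TRAJECTORY_FOLD = 2.0
STAGE_FOLD = 7.5
DETECT_FRAC_MIN = 0.1
LOGFC_MIN = 0.3

#: exhaustive fusion search is used up to this many initial bins (2^(n-1) plans)
_EXHAUSTIVE_MAX_BINS = 15


@dataclass
class Segment:
    interval: tuple[float, float]
    cell_ids: list[str]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class SegmentPartition:
    """Ordered, disjoint pseudotime segments jointly covering the trajectory."""

    segments: list[Segment]
    n_initial: int = 15
    min_cells: int = 60

    def validate(self) -> None:
        total = sum(s.n_cells for s in self.segments)
        seen = set(itertools.chain.from_iterable(s.cell_ids for s in self.segments))
        if len(seen) != total:
            raise ValueError("segments overlap")
        for a, b in itertools.pairwise(self.segments):
            if a.interval[1] > b.interval[0] + 1e-12:
                raise ValueError("segments out of order")
        if total >= self.min_cells:
            for s in self.segments:
                if s.n_cells < self.min_cells:
                    raise ValueError(f"segment {s.interval} has {s.n_cells} < {self.min_cells} cells")


@dataclass
class MarkerCall:
    gene: str
    window: str
    detect_frac: float
    aucpr: float
    aucpr_ratio: float
    logfc: float
    passes: bool


@dataclass
class EnrichedGeneSet:
    cell_type: str
    genes: set[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)


def _fusion_cost(group_counts: list[int]) -> float:
    return float(np.var(group_counts))


def _enumerate_plans(counts: np.ndarray, min_cells: int) -> list[list[int]] | None:
    """All contiguous groupings (as group lengths) with every group total >=
    min_cells; None when even the single-group plan is infeasible."""
    n = len(counts)
    prefix = np.concatenate([[0], np.cumsum(counts)])
    if prefix[-1] < min_cells:
        return None
    plans = []
    for mask in range(1 << (n - 1)):
        bounds = [0] + [i + 1 for i in range(n - 1) if mask >> i & 1] + [n]
        totals = prefix[bounds[1:]] - prefix[bounds[:-1]]
        if np.all(totals >= min_cells):
            plans.append([bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)])
    return plans


def _greedy_plan(counts: np.ndarray, min_cells: int) -> list[int]:
    groups = [[c] for c in counts]
    while len(groups) > 1:
        totals = [sum(g) for g in groups]
        deficient = [i for i, t in enumerate(totals) if t < min_cells]
        if not deficient:
            break
        i = min(deficient, key=lambda k: totals[k])
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:
            j = i - 1 if totals[i - 1] <= totals[i + 1] else i + 1
        lo, hi = sorted((i, j))
        groups[lo : hi + 1] = [groups[lo] + groups[hi]]
    return [len(g) for g in groups]


def segment_pseudotime(
    pseudotime: pd.Series,
    n_segments: int = 15,
    min_cells: int = 60,
) -> SegmentPartition:
    """Divide the pseudotime line into ``n_segments`` equal-width intervals,
    then fuse adjacent under-populated segments so every final segment holds
    at least ``min_cells`` cells with counts as even as possible.

    "As even as possible" is implemented as: among all contiguous fusion
    plans whose groups each reach ``min_cells``, fuse as little as possible
    (maximum number of final segments), breaking ties by the minimum variance
    of the final counts.
    The search is exhaustive for up to 15 initial bins and greedy
    smallest-neighbour merging beyond that. Fewer than ``min_cells`` cells in
    total collapse to a single segment.
    """
    pseudotime = pd.Series(pseudotime).astype(float)
    if len(pseudotime) == 0:
        raise ValueError("at least one cell required")
    lo, hi = float(pseudotime.min()), float(pseudotime.max())
    edges = np.linspace(lo, hi, n_segments + 1)
    if hi == lo:
        bin_of = np.zeros(len(pseudotime), dtype=int)
    else:
        bin_of = np.clip(np.searchsorted(edges, pseudotime.values, side="right") - 1, 0, n_segments - 1)
    counts = np.bincount(bin_of, minlength=n_segments)

    if n_segments <= _EXHAUSTIVE_MAX_BINS:
        plans = _enumerate_plans(counts, min_cells)
    else:
        plans = None if counts.sum() < min_cells else [_greedy_plan(counts, min_cells)]
    if plans is None:
        plan = [n_segments]  # whole trajectory in one segment
    else:
        prefix = np.concatenate([[0], np.cumsum(counts)])

        # fuse as little as possible (max segments), then as evenly as
        # possible (min variance of final counts)
        def key(plan: list[int]) -> tuple[int, float]:
            b = np.concatenate([[0], np.cumsum(plan)])
            return (-len(plan), _fusion_cost(list(prefix[b[1:]] - prefix[b[:-1]])))

        plan = min(plans, key=key)

    segments, start = [], 0
    for width in plan:
        members = pseudotime.index[np.isin(bin_of, range(start, start + width))]
        segments.append(
            Segment(interval=(float(edges[start]), float(edges[start + width])), cell_ids=list(members))
        )
        start += width
    part = SegmentPartition(segments=segments, n_initial=n_segments, min_cells=min_cells)
    part.validate()
    return part


def aucpr(scores, labels) -> float:
    """Area under the precision-recall curve (average precision) of a score
    vector against binary labels, with tied scores contributing as a block.
    The uninformative baseline equals the positive prevalence."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("labels must contain both classes")
    return float(average_precision_score(labels, scores))


def call_markers(
    data: NormalizedMatrix,
    group_cells: list[str],
    background_cells: list[str],
    mode: str = "trajectory",
    window: str = "",
    fold: float | None = None,
    detect_frac_min: float = DETECT_FRAC_MIN,
    logfc_min: float = LOGFC_MIN,
) -> list[MarkerCall]:
    """Score every gene as a marker of ``group_cells`` against
    ``background_cells`` within one pseudotime segment or stage window.

    detect_frac is the fraction of group cells with a nonzero normalized
    value; aucpr_ratio divides AUCPR by the positive prevalence (the analytic
    expectation for an uninformative ranking); logfc is the difference of
    mean log2 expression (group - background).
    """
    if mode not in ("trajectory", "stage"):
        raise ValueError(f"mode must be 'trajectory' or 'stage', got {mode!r}")
    if not group_cells or not background_cells:
        raise ValueError("both cell sets must be non-empty")
    if set(group_cells) & set(background_cells):
        raise ValueError("group and background cells must be disjoint")
    if fold is None:
        fold = TRAJECTORY_FOLD if mode == "trajectory" else STAGE_FOLD

    cells = list(group_cells) + list(background_cells)
    pos = {c: i for i, c in enumerate(data.cell_ids)}
    idx = [pos[c] for c in cells]
    values = data.values[:, idx]
    n_group = len(group_cells)
    labels = np.array([1] * n_group + [0] * len(background_cells))
    prevalence = n_group / len(cells)

    detect = (values[:, :n_group] > 0).mean(axis=1)
    logfc = values[:, :n_group].mean(axis=1) - values[:, n_group:].mean(axis=1)
    calls = []
    for gi, gene in enumerate(data.gene_ids):
        row = values[gi]
        if np.all(row == row[0]):
            ap = prevalence  # constant scores: uninformative by the tie rule
        else:
            ap = aucpr(row, labels)
        ratio = ap / prevalence
        passes = bool(
            detect[gi] >= detect_frac_min and ratio >= fold and logfc[gi] > logfc_min
        )
        calls.append(
            MarkerCall(
                gene=gene,
                window=window,
                detect_frac=float(detect[gi]),
                aucpr=float(ap),
                aucpr_ratio=float(ratio),
                logfc=float(logfc[gi]),
                passes=passes,
            )
        )
    return calls


def define_enriched(
    calls_by_window: list[list[MarkerCall]],
    mode: str,
    cell_type: str = "",
) -> EnrichedGeneSet:
    """Admit genes as trajectory-enriched.

    Trajectory mode: a gene is enriched if it passes in the final pseudotime
    segment, or passes in at least two segments. Stage mode: passing in any
    stage window is sufficient.
    """
    if mode not in ("trajectory", "stage"):
        raise ValueError(f"mode must be 'trajectory' or 'stage', got {mode!r}")
    pass_windows: dict[str, list[int]] = {}
    for wi, calls in enumerate(calls_by_window):
        for call in calls:
            if call.passes:
                pass_windows.setdefault(call.gene, []).append(wi)
    genes: set[str] = set()
    provenance: dict[str, list[str]] = {}
    last = len(calls_by_window) - 1
    for gene, wins in pass_windows.items():
        reasons = []
        if mode == "trajectory":
            if last in wins:
                reasons.append("last-segment")
            if len(wins) >= 2:
                reasons.append(">=2-segments")
        else:
            reasons.append("any-stage")
        if reasons:
            genes.add(gene)
            provenance[gene] = reasons
    return EnrichedGeneSet(cell_type=cell_type, genes=genes, provenance=provenance)


def union_enriched(a: EnrichedGeneSet, b: EnrichedGeneSet) -> EnrichedGeneSet:
    """Union of the enriched genes found from two datasets of the same cell
    type (e.g. the trajectory-mode and stage-mode calls)."""
    if a.cell_type != b.cell_type:
        raise ValueError(f"cell types differ: {a.cell_type!r} vs {b.cell_type!r}")
    provenance = {g: list(r) for g, r in a.provenance.items()}
    for g, r in b.provenance.items():
        provenance[g] = sorted(set(provenance.get(g, [])) | set(r))
    return EnrichedGeneSet(cell_type=a.cell_type, genes=a.genes | b.genes, provenance=provenance)


def fisher_enrichment(
    genes: set[str],
    annotations: AnnotationMap,
    background: set[str],
) -> pd.DataFrame:
    """One-sided over-representation test per term (exact hypergeometric
    tail), against a background gene universe. Terms with no annotated genes
    in the background are skipped. No multiple-testing correction is applied.
    Returns a DataFrame indexed by term with columns k (hits in ``genes``),
    K (hits in background), n, N, direction, p_value, sorted by p_value.
    """
    genes = set(genes)
    background = set(background)
    if not genes <= background:
        raise ValueError(f"genes not contained in background: {sorted(genes - background)[:5]}")
    term_background: dict[str, set[str]] = {}
    for g in background:
        for t in annotations.terms_for(g):
            term_background.setdefault(t, set()).add(g)
    N, n = len(background), len(genes)
    rows = []
    for term, carriers in term_background.items():
        K = len(carriers)
        k = len(carriers & genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        direction = "over" if (k / n) > (K / N) else "under"
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "direction": direction, "p_value": p})
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "direction", "p_value"])
    return df.set_index("term").sort_values("p_value")
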