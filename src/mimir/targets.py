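"""Transcription-factor target inference from perturbation scRNA-seq by
robust linear regression.

Each detected gene in a cell type is modelled as a linear combination of a
constant baseline, the TF expression levels (set to 0 in cells where that TF
was mutated or CRISPR-targeted), an injection covariate (0 uninjected, 1
single-gene gRNAs, 1.5 multi-gene gRNAs) and a batch covariate. Fitting uses
iteratively reweighted M-estimation with Andrew's wave criterion (tuning
constant a = 1.339) and MAD scale; p-values are the per-coefficient
asymptotic normal tests from the robust fit, and R^2 = 1 - SSres/SStot is
computed from the raw (unweighted) residuals. A gene is a positive target of
a TF when R^2 > 0.15, the TF's coefficient exceeds 0.05 and its p-value is
below 1e-9 (negative targets symmetrically). Induced (mis-expression)
targets additionally require a positive call in at least two cell types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import NormalizedMatrix
from .modules import ModulePartition

logger = logging.getLogger(__name__)

R2_MIN = 0.15
COEF_MIN = 0.05
P_MAX = 1e-9
ANDREW_WAVE_A = 1.339
DETECT_MIN_FRAC = 0.01  # response genes must be detected in >= 1% of cells


@dataclass
class DesignMatrix:
    """Cells x predictors design: const, one column per TF (knockout-zeroed
    normalized log2 levels), injection, batch."""

    frame: pd.DataFrame
    tf_names: list[str]

    @property
    def cells(self) -> list[str]:
        return list(self.frame.index)


def build_design(
    cell_meta: pd.DataFrame,
    tf_expression: NormalizedMatrix,
    knockout_map: dict[str, set[str] | frozenset[str]],
    injection_map: dict[str, float] | None = None,
) -> DesignMatrix:
    """Assemble the regression design from per-cell metadata and TF levels.

    ``knockout_map`` names, per condition, the TFs whose predictor is forced
    to 0 in that condition's cells (empty set for controls). ``injection_map``
    overrides the default injection coding derived from the knockout count
    (0 none, 1 one TF, 1.5 several — mis-expression conditions that inject
    mRNA without knocking anything out need the override). Batch labels are
    coerced to numeric codes.
    """
    conditions = cell_meta["condition"].astype(str)
    missing = sorted(set(conditions) - set(knockout_map))
    if missing:
        raise ValueError(f"conditions missing from knockout_map: {missing}")
    tf_names = list(tf_expression.gene_ids)
    cells = list(cell_meta.index)
    sub = tf_expression.subset_cells(cells)
    levels = pd.DataFrame(sub.values.T, index=cells, columns=tf_names)
    for cond, kos in knockout_map.items():
        mask = conditions == cond
        for tf in kos:
            if tf not in levels.columns:
                raise ValueError(f"knockout_map names unknown TF {tf!r}")
            levels.loc[mask.values, tf] = 0.0

    if injection_map is None:
        injection_map = {
            cond: (0.0 if len(kos) == 0 else 1.0 if len(kos) == 1 else 1.5)
            for cond, kos in knockout_map.items()
        }
    injection = conditions.map(injection_map).astype(float)

    batch_raw = cell_meta["batch"]
    batch = pd.to_numeric(batch_raw, errors="coerce")
    if batch.isna().any():
        codes, uniques = pd.factorize(batch_raw.astype(str), sort=True)
        logger.warning("non-numeric batch labels coded as %s", dict(enumerate(uniques)))
        batch = pd.Series(codes, index=cell_meta.index, dtype=float)

    frame = pd.concat(
        [pd.Series(1.0, index=cells, name="const"), levels,
         injection.rename("injection"), batch.rename("batch")],
        axis=1,
    )
    return DesignMatrix(frame=frame, tf_names=tf_names)


@dataclass
class TargetFit:
    """Robust regression result for one response gene."""

    gene: str
    coef: pd.Series
    pvalues: pd.Series
    r2: float
    cell_type: str = ""
    converged: bool = True
    dropped: list[str] = field(default_factory=list)


def fit_robust(
    y: np.ndarray | pd.Series,
    X: DesignMatrix,
    gene: str = "",
    cell_type: str = "",
    maxiter: int = 50,
    tol: float = 1e-8,
) -> TargetFit:
    """M-estimation fit of one gene with Andrew's wave loss.

    Rank-deficient design columns (e.g. a TF zeroed in every cell) are
    dropped with a warning and get NaN coefficients. A constant response is
    returned with R^2 = 0 and nothing significant. Non-convergence within
    ``maxiter`` iterations flags the fit so it can be excluded from calls.
    """
    y = np.asarray(y, dtype=float)
    frame = X.frame
    if len(y) != len(frame):
        raise ValueError("response length does not match design")
    if np.unique(y).size < 2:
        idx = frame.columns
        return TargetFit(
            gene=gene,
            coef=pd.Series(0.0, index=idx),
            pvalues=pd.Series(1.0, index=idx),
            r2=0.0,
            cell_type=cell_type,
        )

    # drop columns that cannot be identified (zero variance other than const,
    # or exact collinearity)
    cols = list(frame.columns)
    keep = ["const"] + [
        c for c in cols if c != "const" and frame[c].nunique() > 1
    ]
    exog = frame[keep].to_numpy()
    rank = np.linalg.matrix_rank(exog)
    while rank < exog.shape[1]:
        for j in range(exog.shape[1] - 1, 0, -1):
            trial = np.delete(exog, j, axis=1)
            if np.linalg.matrix_rank(trial) == rank:
                del keep[j]
                exog = trial
                break
        rank = np.linalg.matrix_rank(exog)
    dropped = [c for c in cols if c not in keep]
    if dropped:
        logger.warning("gene %s: dropped rank-deficient predictors %s", gene, dropped)

    model = sm.RLM(y, exog, M=sm.robust.norms.AndrewWave(a=ANDREW_WAVE_A))
    res = model.fit(maxiter=maxiter, tol=tol, conv="coefs")
    n_iter = len(model.fit_history.get("params", [])) if hasattr(model, "fit_history") else 0
    converged = n_iter < maxiter

    params = pd.Series(np.nan, index=cols)
    pvals = pd.Series(np.nan, index=cols)
    params[keep] = res.params
    pvals[keep] = res.pvalues

    resid = y - exog @ res.params
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sstot == 0 else float(1.0 - np.sum(resid**2) / sstot)
    return TargetFit(gene=gene, coef=params, pvalues=pvals, r2=r2,
                     cell_type=cell_type, converged=converged, dropped=dropped)


@dataclass
class TargetSets:
    """Per-TF positive/negative target calls for one cell type."""

    cell_type: str
    positive: dict[str, set[str]] = field(default_factory=dict)
    negative: dict[str, set[str]] = field(default_factory=dict)

    def all_targets(self, tf: str | None = None) -> set[str]:
        tfs = [tf] if tf is not None else sorted(set(self.positive) | set(self.negative))
        out: set[str] = set()
        for t in tfs:
            out |= self.positive.get(t, set()) | self.negative.get(t, set())
        return out


def call_targets(
    fits: list[TargetFit],
    tf_names: list[str],
    r2_min: float = R2_MIN,
    coef_min: float = COEF_MIN,
    p_max: float = P_MAX,
    cell_type: str = "",
) -> TargetSets:
    """Threshold fits into per-TF target sets.

    Positive target: R^2 > r2_min AND coefficient > coef_min AND p < p_max;
    negative targets use coefficient < -coef_min. Non-converged fits are
    excluded."""
    sets = TargetSets(cell_type=cell_type,
                      positive={tf: set() for tf in tf_names},
                      negative={tf: set() for tf in tf_names})
    for f in fits:
        if not f.converged or f.r2 <= r2_min:
            continue
        for tf in tf_names:
            c, p = f.coef.get(tf, np.nan), f.pvalues.get(tf, np.nan)
            if not (np.isfinite(c) and np.isfinite(p)) or p >= p_max:
                continue
            if c > coef_min:
                sets.positive[tf].add(f.gene)
            elif c < -coef_min:
                sets.negative[tf].add(f.gene)
    return sets


def call_induced_targets(
    target_sets_by_cell_type: list[TargetSets],
    min_cell_types: int = 2,
) -> dict[str, set[str]]:
    """Mis-expression consensus: a gene is an induced target of a TF when it
    is a positive target in at least ``min_cell_types`` cell types."""
    counts: dict[str, dict[str, int]] = {}
    for ts in target_sets_by_cell_type:
        for tf, genes in ts.positive.items():
            for g in genes:
                counts.setdefault(tf, {}).setdefault(g, 0)
                counts[tf][g] += 1
    return {
        tf: {g for g, n in per_gene.items() if n >= min_cell_types}
        for tf, per_gene in counts.items()
    }


def classify_targets(
    targets_a: set[str],
    targets_b: set[str],
    enrichment: dict[str, str],
    cell_type_a: str,
    cell_type_b: str,
) -> dict[str, set[str]]:
    """Split two TF programs' targets into shared / A-specific / B-specific.

    shared = regulated in both programs; A-specific = targets of A only,
    restricted to genes whose higher-expression cell type is A's
    (``enrichment`` maps gene -> preferred cell type); symmetrically for B.
    Genes specific to one program but preferring the other cell type are
    returned under "unclassified"."""
    shared = targets_a & targets_b
    a_only = targets_a - targets_b
    b_only = targets_b - targets_a
    a_specific = {g for g in a_only if enrichment.get(g) == cell_type_a}
    b_specific = {g for g in b_only if enrichment.get(g) == cell_type_b}
    unclassified = (a_only - a_specific) | (b_only - b_specific)
    return {
        "shared": shared,
        "a_specific": a_specific,
        "b_specific": b_specific,
        "unclassified": unclassified,
    }


def target_module_overlap(targets: set[str], partition: ModulePartition) -> pd.DataFrame:
    """Per module, the percentage of member genes that are targets, ranked
    descending (ties by module id)."""
    universe = set(partition.assignments)
    if not targets & universe:
        raise ValueError("targets and partition share no genes")
    rows = []
    for m, size in partition.module_sizes.items():
        members = set(partition.members(m))
        hits = len(members & targets)
        rows.append({"module": m, "n_genes": size, "n_targets": hits,
                     "target_pct": 100.0 * hits / size})
    df = pd.DataFrame(rows).set_index("module")
    return df.sort_values(by=["target_pct", "module"], ascending=[False, True])


class TargetRegressionModel:
    """Robust TF-target regression over all detected response genes in one
    cell type (statsmodels-style model object)."""

    def __init__(
        self,
        data: NormalizedMatrix,
        design: DesignMatrix,
        genes: list[str] | None = None,
        cell_type: str = "",
        detect_min_frac: float = DETECT_MIN_FRAC,
    ):
        self.data = data.subset_cells(design.cells)
        self.design = design
        self.cell_type = cell_type
        tfs = set(design.tf_names)
        if genes is None:
            genes = [g for g in data.gene_ids if g not in tfs]
        else:
            kept = [g for g in genes if g not in tfs]
            if len(kept) < len(genes):
                logger.warning("TFs excluded from the response gene set: %s",
                               sorted(set(genes) - set(kept)))
            genes = kept
        detect = (self.data.values > 0).mean(axis=1)
        gidx = {g: i for i, g in enumerate(self.data.gene_ids)}
        self.genes = [g for g in genes if detect[gidx[g]] >= detect_min_frac]

    def fit(self, maxiter: int = 50, tol: float = 1e-8) -> "TargetRegressionResults":
        gidx = {g: i for i, g in enumerate(self.data.gene_ids)}
        fits = [
            fit_robust(self.data.values[gidx[g]], self.design, gene=g,
                       cell_type=self.cell_type, maxiter=maxiter, tol=tol)
            for g in self.genes
        ]
        return TargetRegressionResults(self, fits)


class TargetRegressionResults:
    """Collection of per-gene robust fits with target-calling helpers."""

    def __init__(self, model: TargetRegressionModel, fits: list[TargetFit]):
        self.model = model
        self.fits = fits

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            row = {"gene": f.gene, "r2": f.r2, "converged": f.converged}
            for tf in self.model.design.tf_names:
                row[f"coef_{tf}"] = f.coef.get(tf, np.nan)
                row[f"p_{tf}"] = f.pvalues.get(tf, np.nan)
            rows.append(row)
        return pd.DataFrame(rows).set_index("gene")

    def call_targets(self, r2_min: float = R2_MIN, coef_min: float = COEF_MIN,
                     p_max: float = P_MAX) -> TargetSets:
        return call_targets(self.fits, self.model.design.tf_names,
                            r2_min=r2_min, coef_min=coef_min, p_max=p_max,
                            cell_type=self.model.cell_type)

    def summary(self) -> str:
        ts = self.call_targets()
        lines = [
            "Robust TF-target regression",
            "===========================",
            f"cell type:       {self.model.cell_type or '<unset>'}",
            f"response genes:  {len(self.fits)}",
            f"cells:           {len(self.model.design.cells)}",
            f"TF predictors:   {', '.join(self.model.design.tf_names)}",
            f"converged fits:  {sum(f.converged for f in self.fits)}",
        ]
        for tf in self.model.design.tf_names:
            lines.append(
                f"  {tf}: {len(ts.positive.get(tf, set()))} positive, "
                f"{len(ts.negative.get(tf, set()))} negative targets"
            )
        return "\n".join(lines)
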