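"""Synthetic trajectory, annotation, interaction and perturbation datasets
with planted ground truth.

Every generator is a pure function of its configuration (all randomness flows
from ``SimulationConfig.seed``), so downstream recovery tests are exactly
reproducible. The trajectory generator uses the same double-sigmoid impulse
parameterization as the temporal fitter in :mod:`mimir.dynamics`, which keeps
onset/offset recovery tests self-consistent.

What is emulated: pseudotime-ordered expression with impulse dynamics, planted
modules that are simultaneously co-expressed and co-annotated (with confounder
settings), a non-target background cell population, and perturbation samples
with TF-zeroed knockouts, linear target responses, injection/batch offsets and
overdispersed count noise. Not emulated: ambient RNA, doublets, or
library-size confounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AnnotationMap, CountMatrix, EvidenceChannels, OntologyDAG
import networkx as nx

CONFOUNDER_MODES = ("none", "co_expressed_split_function", "co_function_split_time", "both")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs shared by all generators.

    noise_sd is the s.d. of multiplicative lognormal noise on expression
    means (log2 scale); dispersion is the negative-binomial size parameter
    (variance = m + m^2/dispersion; ``inf`` with ``noise_sd=0`` yields the
    deterministic noise-free limit). annotation_purity is the probability a
    module gene is annotated with its own module's term rather than a random
    one. effect_size scales the planted TF-target regression coefficients.
    """

    seed: int = 0
    n_modules: int = 10
    genes_per_module: int = 20
    n_background_genes: int = 200
    n_cells: int = 1000
    n_bins: int = 15
    noise_sd: float = 0.1
    dispersion: float = 10.0
    annotation_purity: float = 0.9
    annotation_coverage: float = 0.6
    confounder_mode: str = "none"
    effect_size: float = 0.5
    outlier_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.n_modules <= 0 or self.genes_per_module <= 0 or self.n_cells <= 0:
            raise ValueError("counts must be positive")
        if self.n_background_genes < 0 or self.n_bins <= 0:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0 or self.dispersion <= 0:
            raise ValueError("noise_sd must be >= 0 and dispersion > 0")
        for p in (self.annotation_purity, self.annotation_coverage, self.outlier_frac):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.confounder_mode not in CONFOUNDER_MODES:
            raise ValueError(f"confounder_mode must be one of {CONFOUNDER_MODES}")
        if self.confounder_mode in ("co_expressed_split_function", "co_function_split_time"):
            if self.n_modules < 2:
                raise ValueError("confounders need at least 2 modules")
        if self.confounder_mode == "both" and self.n_modules < 4:
            raise ValueError("'both' confounders need at least 4 modules")


@dataclass
class GroundTruth:
    """Generative parameters the downstream stages are asked to recover."""

    true_partition: dict[str, str] = field(default_factory=dict)
    true_onset: dict[str, float] = field(default_factory=dict)
    true_offset: dict[str, float] = field(default_factory=dict)
    true_markers: set[str] = field(default_factory=set)
    true_targets: dict[tuple[str, str], float] = field(default_factory=dict)
    module_onset: dict[str, float] = field(default_factory=dict)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def impulse_curve(
    t: np.ndarray,
    h0: float,
    h1: float,
    h2: float,
    t1: float,
    t2: float,
    b1: float,
    b2: float,
) -> np.ndarray:
    """Double-sigmoid impulse: rise from h0 toward peak h1 at t1, fall toward
    the late plateau h2 at t2. Shared with the fitter in :mod:`mimir.dynamics`.
    """
    rise = h0 + (h1 - h0) * _sigmoid(b1 * (t - t1))
    fall = h2 + (h1 - h2) * _sigmoid(b2 * (t2 - t))
    return rise * fall / h1


def _module_timing(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Module-level onsets/offsets spread over the trajectory; confounded
    module pairs get their timing tied (co-expressed) as required."""
    if cfg.n_modules == 1:
        onsets = np.array([0.3])
    else:
        onsets = np.linspace(0.05, 0.80, cfg.n_modules)
    offsets = onsets + 0.18
    if cfg.confounder_mode in ("co_expressed_split_function", "both"):
        onsets[1] = onsets[0]
        offsets[1] = offsets[0]
    return onsets, offsets


def _co_function_pair(cfg: SimulationConfig) -> tuple[int, int] | None:
    # the shared-term pair is planted on modules with well-separated onsets
    # (functionally similar but temporally distant)
    if cfg.confounder_mode == "co_function_split_time":
        return (0, cfg.n_modules - 1)
    if cfg.confounder_mode == "both":
        return (2, cfg.n_modules - 2)
    return None


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    mean = np.clip(mean, 0.0, None)
    if cfg.noise_sd > 0:
        mean = mean * np.exp2(rng.normal(0.0, cfg.noise_sd, size=mean.shape))
    if np.isinf(cfg.dispersion):
        if cfg.noise_sd == 0:
            return np.round(mean).astype(np.int64)
        return rng.poisson(mean).astype(np.int64)
    r = cfg.dispersion
    p = r / (r + np.clip(mean, 1e-12, None))
    out = rng.negative_binomial(r, p)
    out[mean == 0] = 0
    return out.astype(np.int64)


def simulate_trajectory_dataset(cfg: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Pseudotime-ordered counts for one trajectory plus a flat background
    cell population, with planted impulse-dynamic modules.

    Module genes follow module-shared onset/offset curves with small per-gene
    jitter and are (near-)silent in the background population, so they are
    the planted trajectory markers. Background genes are expressed at a
    constant mean in every cell.
    """
    rng = np.random.default_rng(cfg.seed)
    onsets, offsets = _module_timing(cfg)

    module_genes = [
        f"mod{m}_g{j}" for m in range(cfg.n_modules) for j in range(cfg.genes_per_module)
    ]
    background_genes = [f"bg_{k}" for k in range(cfg.n_background_genes)]
    genes = module_genes + background_genes

    # the non-trajectory background outnumbers the trajectory (as non-axial
    # cells do in an embryo); this keeps the per-window marker prevalence low
    # enough that an AUCPR fold criterion >= 2 is attainable at all
    n_traj = cfg.n_cells
    n_back = 3 * cfg.n_cells
    pt_traj = np.sort(rng.uniform(0.0, 1.0, n_traj))
    pt_back = np.sort(rng.uniform(0.0, 1.0, n_back))
    cells = [f"traj_{i}" for i in range(n_traj)] + [f"back_{i}" for i in range(n_back)]

    truth = GroundTruth()
    mean = np.zeros((len(genes), n_traj + n_back))
    for m in range(cfg.n_modules):
        mid = f"M{m}"
        truth.module_onset[mid] = float(onsets[m])
        for j in range(cfg.genes_per_module):
            g = f"mod{m}_g{j}"
            t1 = float(np.clip(onsets[m] + rng.normal(0, 0.02), 0.02, 0.95))
            t2 = float(max(np.clip(offsets[m] + rng.normal(0, 0.02), 0.05, 1.2), t1 + 0.05))
            amp = rng.uniform(20.0, 80.0)
            h2 = rng.uniform(0.0, 0.005)
            gi = m * cfg.genes_per_module + j
            mean[gi, :n_traj] = amp * impulse_curve(pt_traj, 0.0, 1.0, h2, t1, t2, 60.0, 60.0)
            truth.true_partition[g] = mid
            truth.true_onset[g] = t1
            truth.true_offset[g] = t2
            truth.true_markers.add(g)
    for k, g in enumerate(background_genes):
        amp = rng.uniform(5.0, 50.0)
        mean[len(module_genes) + k, :] = amp

    counts = _draw_counts(rng, mean, cfg)
    meta = pd.DataFrame(
        {
            "pseudotime": np.concatenate([pt_traj, pt_back]),
            "stage": ["s0"] * (n_traj + n_back),
            "cell_type": ["trajectory"] * n_traj + ["background"] * n_back,
            "condition": ["control"] * (n_traj + n_back),
            "batch": ["b0"] * (n_traj + n_back),
        },
        index=cells,
    )
    return CountMatrix(gene_ids=genes, cell_ids=cells, counts=counts, cell_meta=meta), truth


def simulate_annotations(
    cfg: SimulationConfig, truth: GroundTruth, n_databases: int = 2
) -> tuple[OntologyDAG, list[AnnotationMap], EvidenceChannels]:
    """Shallow ontology (one term per module under a single root, plus
    distractor terms), per-database gene annotations, and within-module
    interaction evidence.

    Under ``co_expressed_split_function`` the tied-timing module pair gets
    disjoint terms and no cross-module interaction evidence; under
    ``co_function_split_time`` a disjoint-timing module pair shares one term.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    root = "T:ROOT"
    graph = nx.DiGraph()
    graph.add_node(root)
    module_term = {f"M{m}": f"T:MOD{m}" for m in range(cfg.n_modules)}
    cofunc = _co_function_pair(cfg)
    if cofunc is not None:
        module_term[f"M{cofunc[1]}"] = module_term[f"M{cofunc[0]}"]
    distractors = [f"T:RAND{k}" for k in range(cfg.n_modules)]
    # each leaf term sits at depth 2 under its own branch, the way unrelated
    # processes sit far apart in a real ontology; two distinct leaves then
    # share only the root, with semantic similarity well below the prior
    for term in set(module_term.values()) | set(distractors):
        branch = term.replace("T:", "T:BR_")
        graph.add_edge(branch, root, relation="is_a")
        graph.add_edge(term, branch, relation="is_a")
    dag = OntologyDAG(graph=graph, names={t: t for t in graph.nodes})

    maps = []
    for d in range(n_databases):
        gene_to_terms: dict[str, frozenset[str]] = {}
        for g, mid in truth.true_partition.items():
            if rng.random() >= cfg.annotation_coverage:
                continue  # gene unannotated in this database
            if rng.random() < cfg.annotation_purity:
                term = module_term[mid]
            else:
                term = distractors[rng.integers(len(distractors))]
            gene_to_terms[g] = frozenset({term})
        maps.append(AnnotationMap(database_name=f"db{d}", gene_to_terms=gene_to_terms))

    by_module: dict[str, list[str]] = {}
    for g, mid in truth.true_partition.items():
        by_module.setdefault(mid, []).append(g)
    records: dict[tuple[str, str], dict[str, float]] = {}
    for mid, members in by_module.items():
        members = sorted(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                chans = {}
                if rng.random() < 0.9:
                    chans["experiments"] = float(rng.uniform(0.8, 0.98))
                if rng.random() < 0.6:
                    chans["coexpression"] = float(rng.uniform(0.6, 0.9))
                if chans:
                    records[(members[i], members[j])] = chans
    # sparse, weak cross-module noise links
    all_genes = sorted(truth.true_partition)
    n_noise = max(1, len(all_genes) // 2)
    for _ in range(n_noise):
        a, b = rng.choice(all_genes, size=2, replace=False)
        if truth.true_partition[a] == truth.true_partition[b]:
            continue
        records.setdefault((a, b), {})["experiments"] = float(rng.uniform(0.15, 0.4))
    return dag, maps, EvidenceChannels.from_records(records)


@dataclass(frozen=True)
class ConditionSpec:
    """One perturbation sample: which TFs are knocked out, the injection
    covariate (0 uninjected, 1 single-gene gRNAs, 1.5 multi-gene gRNAs), the
    collection batch, and how many cells it contributes."""

    name: str
    knockout: frozenset[str] = frozenset()
    injection: float = 0.0
    batch: int = 0
    n_cells: int | None = None


def default_perturbation_conditions(n_tfs: int, n_cells: int | None = None) -> list[ConditionSpec]:
    """Control, one single-TF crispant per TF, and one all-TF crispant."""
    tfs = [f"TF{i}" for i in range(n_tfs)]
    conds = [ConditionSpec("control", frozenset(), 0.0, 0, n_cells)]
    for i, tf in enumerate(tfs):
        conds.append(ConditionSpec(f"{tf}_crispant", frozenset({tf}), 1.0, i % 2, n_cells))
    if n_tfs > 1:
        conds.append(ConditionSpec("all_crispant", frozenset(tfs), 1.5, 1, n_cells))
    return conds


def simulate_perturbation_dataset(
    cfg: SimulationConfig,
    n_tfs: int,
    conditions: list[ConditionSpec] | None = None,
    n_targets: int = 40,
    cell_type: str = "typeA",
) -> tuple[CountMatrix, GroundTruth]:
    """Perturbation scRNA-seq with TF-zeroed knockout conditions and linear
    target responses.

    Each target gene's log2 mean is baseline + coefficient x TF level +
    injection and batch offsets; non-targets depend on injection/batch (real
    confounds the regression design must absorb) but on no TF. An
    ``outlier_frac`` fraction of cells carries gross additive outliers on a
    random tenth of genes. Housekeeping filler genes stabilise library sizes.
    """
    if conditions is None:
        conditions = default_perturbation_conditions(n_tfs)
    tfs = [f"TF{i}" for i in range(n_tfs)]
    for spec in conditions:
        unknown = spec.knockout - set(tfs)
        if unknown:
            raise ValueError(f"condition {spec.name!r} knocks out unknown TFs {sorted(unknown)}")
    if n_targets > cfg.n_background_genes:
        raise ValueError("n_targets exceeds the response-gene budget (n_background_genes)")

    rng = np.random.default_rng(cfg.seed + 2)
    response_genes = [f"gene_{k}" for k in range(cfg.n_background_genes)]
    hk_genes = [f"hk_{k}" for k in range(50)]
    genes = tfs + response_genes + hk_genes

    truth = GroundTruth()
    coef = np.zeros((n_tfs, len(response_genes)))
    target_idx = rng.choice(len(response_genes), size=n_targets, replace=False)
    for rank, gi in enumerate(sorted(target_idx)):
        tf_i = rank % n_tfs
        sign = -1.0 if rng.random() < 0.25 else 1.0
        c = sign * cfg.effect_size * rng.uniform(0.8, 1.2)
        coef[tf_i, gi] = c
        truth.true_targets[(tfs[tf_i], response_genes[gi])] = float(c)

    base = rng.uniform(1.5, 3.5, size=len(response_genes))
    # negatively regulated targets need headroom so repression is not clipped
    # at zero expression
    for tf_i, gi in zip(*np.nonzero(coef < 0)):
        base[gi] = rng.uniform(4.5, 6.0)
    inj_eff = rng.normal(0.0, 0.15, size=len(response_genes))
    batch_eff = rng.normal(0.0, 0.15, size=len(response_genes))
    hk_amp = rng.uniform(400.0, 1000.0, size=len(hk_genes))

    blocks, meta_rows, cell_names = [], [], []
    for spec in conditions:
        n = spec.n_cells if spec.n_cells is not None else cfg.n_cells
        tf_level = np.clip(rng.normal(5.0, 0.8, size=(n_tfs, n)), 0.0, None)
        for i, tf in enumerate(tfs):
            if tf in spec.knockout:
                tf_level[i, :] = 0.0
        logmean = (
            base[:, None]
            + coef.T @ tf_level
            + inj_eff[:, None] * spec.injection
            + batch_eff[:, None] * spec.batch
        )
        if cfg.outlier_frac > 0:
            out_cells = rng.random(n) < cfg.outlier_frac
            for ci in np.flatnonzero(out_cells):
                hit = rng.random(len(response_genes)) < 0.25
                logmean[hit, ci] += 7.0
        mean_resp = np.exp2(np.clip(logmean, 0.0, 16.0)) - 1.0
        mean_tf = np.exp2(tf_level) - 1.0
        mean_hk = np.repeat(hk_amp[:, None], n, axis=1)
        mean = np.vstack([mean_tf, mean_resp, mean_hk])
        blocks.append(_draw_counts(rng, mean, cfg))
        for j in range(n):
            cell_names.append(f"{spec.name}_c{j}")
            meta_rows.append(
                {
                    "pseudotime": np.nan,
                    "stage": "s0",
                    "cell_type": cell_type,
                    "condition": spec.name,
                    "batch": str(spec.batch),
                }
            )
    counts = np.hstack(blocks)
    meta = pd.DataFrame(meta_rows, index=cell_names)
    return CountMatrix(gene_ids=genes, cell_ids=cell_names, counts=counts, cell_meta=meta), truth


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: the same configuration under a different seed."""
    return replace(cfg, seed=seed)
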