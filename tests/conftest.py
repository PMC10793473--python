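import networkx as nx
import numpy as np
import pytest

import mimir
from mimir.io import OntologyDAG


@pytest.fixture(scope="session")
def toy_dag() -> OntologyDAG:
    """Three-term ontology: A is_a R, B is_a R."""
    g = nx.DiGraph()
    g.add_edge("A", "R", relation="is_a")
    g.add_edge("B", "R", relation="is_a")
    return OntologyDAG(graph=g, names={t: t for t in "ABR"})


@pytest.fixture(scope="session")
def low_noise_cfg() -> mimir.SimulationConfig:
    """The low-noise trajectory study conditions: 10 modules x 20 genes,
    200 flat background genes, 1000 trajectory cells."""
    return mimir.SimulationConfig(seed=0, noise_sd=0.05, dispersion=50.0)


@pytest.fixture(scope="session")
def trajectory_sim(low_noise_cfg):
    counts, truth = mimir.simulate_trajectory_dataset(low_noise_cfg)
    return counts, truth


@pytest.fixture(scope="session")
def normalized_trajectory(trajectory_sim):
    counts, truth = trajectory_sim
    return mimir.normalize_counts(counts), truth


@pytest.fixture(scope="session")
def marker_calls(normalized_trajectory):
    """Per-segment marker calls of trajectory vs background cells."""
    norm, truth = normalized_trajectory
    meta = norm.cell_meta
    traj = list(meta.index[meta.cell_type == "trajectory"])
    segments = mimir.segment_pseudotime(meta.loc[traj, "pseudotime"].astype(float))
    bg_pt = meta.loc[meta.cell_type == "background", "pseudotime"].astype(float)
    calls_by_window = []
    for si, seg in enumerate(segments.segments):
        lo, hi = seg.interval
        background = list(bg_pt.index[(bg_pt >= lo) & (bg_pt <= hi)])
        calls_by_window.append(
            mimir.call_markers(norm, seg.cell_ids, background, mode="trajectory", window=f"s{si}")
        )
    return segments, calls_by_window, truth


@pytest.fixture(scope="session")
def confounded_pipeline():
    """Full module-detection inputs under both confounders (fixed seed)."""
    cfg = mimir.SimulationConfig(
        seed=0, noise_sd=0.05, dispersion=50.0, confounder_mode="both", annotation_purity=0.9
    )
    counts, truth = mimir.simulate_trajectory_dataset(cfg)
    dag, maps, interaction = mimir.simulate_annotations(cfg, truth)
    norm = mimir.normalize_counts(counts)
    meta = norm.cell_meta
    traj = list(meta.index[meta.cell_type == "trajectory"])
    segments = mimir.segment_pseudotime(meta.loc[traj, "pseudotime"].astype(float))
    genes = sorted(truth.true_partition)
    profile = mimir.build_profiles(
        norm.subset_cells(traj), segments, genes, exclude_presegment=True
    )
    evidence = mimir.assemble_channels(interaction, maps, dag, genes=genes)
    model = mimir.GeneModuleModel.from_profiles(profile, evidence, metric="jsd", logic="and")
    return {"model": model, "truth": truth, "profile": profile, "evidence": evidence}


@pytest.fixture(scope="session")
def perturbation_sim():
    """Perturbation dataset: 2 TFs, 40 planted targets, 5% outlier cells."""
    cfg = mimir.SimulationConfig(
        seed=0, n_cells=300, effect_size=0.5, outlier_frac=0.05, noise_sd=0.1, dispersion=10.0
    )
    conditions = mimir.default_perturbation_conditions(2)
    counts, truth = mimir.simulate_perturbation_dataset(cfg, n_tfs=2, conditions=conditions)
    return counts, truth, conditions


@pytest.fixture(scope="session")
def perturbation_fit(perturbation_sim):
    counts, truth, conditions = perturbation_sim
    norm = mimir.normalize_counts(counts)
    tfs = ["TF0", "TF1"]
    idx = [norm.gene_ids.index(t) for t in tfs]
    tf_expr = mimir.NormalizedMatrix(
        tfs, list(norm.cell_ids), norm.values[idx], norm.cell_meta, norm.scale_total
    )
    design = mimir.build_design(
        norm.cell_meta, tf_expr, {c.name: set(c.knockout) for c in conditions}
    )
    results = mimir.TargetRegressionModel(norm, design, cell_type="typeA").fit()
    return norm, design, results, truth


def average_precision_oracle(scores, labels) -> float:
    """Brute-force precision-recall integrator: walk the descending-score
    ranking cut by cut, accumulating precision x recall increments (ties
    processed as one block). Independent of the library implementation."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    n_pos = labels.sum()
    ap = 0.0
    tp = fp = 0
    i = 0
    prev_recall = 0.0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tp += int(labels[i:j].sum())
        fp += (j - i) - int(labels[i:j].sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap
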