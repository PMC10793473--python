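"""Functional similarity between genes: graph-based semantic similarity of
their annotation terms (Wang's measure combined by best-match average), one
evidence channel per annotation database, fused with interaction-database
channels under a fixed-prior correction.

Wang's measure scores two ontology terms by the weight-decayed contributions
of their shared ancestors: within a term's ancestor closure, the term itself
gets S-value 1 and every ancestor the maximum over outgoing paths of the
product of relation weights (is_a 0.8, part_of 0.6 by default). The
similarity is the sum of both terms' S-values over their common ancestors,
divided by the sum of all S-values of each.

Channels are combined as the complement-product of prior-removed scores:
with prior p, s_i' = max(0, (S_i - p) / (1 - p)) and
S_total = 1 - (1 - p) * prod_i (1 - s_i'). A pair whose channels all sit at
the prior stays at the prior; any channel at 1 is absorbing; a pair with no
evidence at all gets functional similarity 0 (not the prior — emitting p for
every conceivable pair would connect the whole gene graph).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import SimilarityMatrix
from .io import AnnotationMap, EvidenceChannels, OntologyDAG, _pair_key

DEFAULT_RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


def _svalues(dag: OntologyDAG, term: str, weights: dict[str, float]) -> dict[str, float]:
    """S-values of ``term``'s ancestor closure (term itself included)."""
    if term not in dag:
        raise KeyError(f"unknown term {term!r}")
    s = {term: 1.0}
    # relax child -> parent contributions to a fixpoint; the graph is a DAG so
    # at most |closure| sweeps are needed and in practice very few
    frontier = [term]
    while frontier:
        nxt = []
        for t in frontier:
            for parent, relation in dag.parents(t):
                w = weights.get(relation)
                if w is None:
                    continue
                cand = w * s[t]
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
                    nxt.append(parent)
        frontier = nxt
    return s


@dataclass
class TermSimilarityCache:
    """Memoises S-value closures and pairwise term similarities for one DAG."""

    dag: OntologyDAG
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RELATION_WEIGHTS))
    _closures: dict[str, dict[str, float]] = field(default_factory=dict, repr=False)
    _pairs: dict[tuple[str, str], float] = field(default_factory=dict, repr=False)

    def closure(self, term: str) -> dict[str, float]:
        if term not in self._closures:
            self._closures[term] = _svalues(self.dag, term, self.weights)
        return self._closures[term]

    def term_similarity(self, a: str, b: str) -> float:
        key = _pair_key(a, b)
        if key not in self._pairs:
            self._pairs[key] = wang_term_similarity(self.dag, a, b, self.weights)
        return self._pairs[key]


def wang_term_similarity(
    dag: OntologyDAG,
    a: str,
    b: str,
    weights: dict[str, float] | None = None,
) -> float:
    """Wang's semantic similarity between two ontology terms in [0, 1]."""
    weights = dict(DEFAULT_RELATION_WEIGHTS) if weights is None else weights
    sa = _svalues(dag, a, weights)
    sb = _svalues(dag, b, weights)
    common = sa.keys() & sb.keys()
    if not common:
        return 0.0
    num = sum(sa[c] + sb[c] for c in common)
    return float(num / (sum(sa.values()) + sum(sb.values())))


def bma_gene_similarity(
    terms_a: frozenset[str] | set[str],
    terms_b: frozenset[str] | set[str],
    cache: TermSimilarityCache,
) -> float | None:
    """Best-match average of pairwise term similarities between two genes'
    term sets; ``None`` (missing evidence, not zero) when either set is
    empty."""
    if not terms_a or not terms_b:
        return None
    ta, tb = sorted(terms_a), sorted(terms_b)
    sims = np.array([[cache.term_similarity(x, y) for y in tb] for x in ta])
    best_a = sims.max(axis=1).sum()
    best_b = sims.max(axis=0).sum()
    return float((best_a + best_b) / (len(ta) + len(tb)))


def assemble_channels(
    interaction: EvidenceChannels | None,
    semantic_maps: list[AnnotationMap],
    dag_per_map: list[OntologyDAG] | OntologyDAG,
    genes: list[str] | None = None,
    weights: dict[str, float] | None = None,
) -> EvidenceChannels:
    """Add one semantic channel per annotation database to the interaction
    channels.

    The semantic channel of a pair is the BMA gene similarity in that
    database; it is missing where either gene is unannotated there. Pairs
    with no channel from any source are absent from the output. ``genes``
    restricts the pair universe (default: every gene seen in the interaction
    table or any annotation map).
    """
    if isinstance(dag_per_map, OntologyDAG):
        dag_per_map = [dag_per_map] * len(semantic_maps)
    if len(dag_per_map) != len(semantic_maps):
        raise ValueError("need one ontology per annotation map")
    inter_names = set(interaction.channel_names) if interaction is not None else set()
    sem_names = [m.database_name for m in semantic_maps]
    if len(set(sem_names)) != len(sem_names) or inter_names & set(sem_names):
        raise ValueError("channel names must be unique across sources")

    if genes is None:
        universe: set[str] = set()
        if interaction is not None:
            for a, b in interaction.pairs:
                universe.update((a, b))
        for m in semantic_maps:
            universe.update(m.gene_to_terms)
        genes = sorted(universe)

    records: dict[tuple[str, str], dict[str, float]] = {}
    if interaction is not None:
        gene_set = set(genes)
        for (a, b) in interaction.pairs:
            if a in gene_set and b in gene_set:
                chans = interaction.channels_for(a, b)
                if chans:
                    records[(a, b)] = dict(chans)

    caches = [TermSimilarityCache(dag=d, weights=weights or dict(DEFAULT_RELATION_WEIGHTS)) for d in dag_per_map]
    for m, cache in zip(semantic_maps, caches):
        annotated = [g for g in genes if m.terms_for(g)]
        for i in range(len(annotated)):
            for j in range(i + 1, len(annotated)):
                a, b = annotated[i], annotated[j]
                val = bma_gene_similarity(m.terms_for(a), m.terms_for(b), cache)
                if val is not None:
                    records.setdefault(_pair_key(a, b), {})[m.database_name] = val
    prior = interaction.prior if interaction is not None else 0.41
    return EvidenceChannels.from_records(records, prior=prior)


def combine_channel_scores(scores: list[float] | dict[str, float], prior: float = 0.41) -> float:
    """Prior-corrected combination of one pair's channel scores."""
    vals = np.asarray(list(scores.values()) if isinstance(scores, dict) else scores, dtype=float)
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("channel scores must lie in [0, 1]")
    s_prime = np.clip((vals - prior) / (1.0 - prior), 0.0, None)
    return float(1.0 - (1.0 - prior) * np.prod(1.0 - s_prime))


def combine_channels(ev: EvidenceChannels, genes: list[str] | None = None) -> SimilarityMatrix:
    """Fuse all evidence channels into the functional similarity S_fun.

    Returns a symmetric matrix over ``genes`` (default: all genes occurring
    in the evidence table) with unit diagonal; pairs carrying no channel get
    similarity 0.
    """
    p = ev.prior
    table = ev.table
    vals = table.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("channel scores must lie in [0, 1]")
    s_prime = np.clip((vals - p) / (1.0 - p), 0.0, None)
    s_prime = np.where(np.isnan(vals), 0.0, s_prime)  # missing channel: skipped
    has_any = (~np.isnan(vals)).any(axis=1) if vals.size else np.array([], dtype=bool)
    total = 1.0 - (1.0 - p) * np.prod(1.0 - s_prime, axis=1)
    total = np.where(has_any, total, 0.0)

    if genes is None:
        universe: set[str] = set()
        for a, b in table.index:
            universe.update((a, b))
        genes = sorted(universe)
    gidx = {g: i for i, g in enumerate(genes)}
    S = np.zeros((len(genes), len(genes)))
    for (a, b), s in zip(table.index, total):
        ia, ib = gidx.get(a), gidx.get(b)
        if ia is None or ib is None:
            continue
        S[ia, ib] = S[ib, ia] = s
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(gene_ids=list(genes), values=S, kind="functional")
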