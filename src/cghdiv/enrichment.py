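"""GO-category representation tests for diverged gene sets.

Annotations are propagated up the term DAG (true-path rule), then each term
is tested for over- and under-representation of a gene set within a universe
by the hypergeometric distribution.  Also builds the per-species sets of
highly diverged genes (greater than k-fold hybridization reduction) and
their cross-species intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigurationError
from .synthetic import NO_HIT


@dataclass
class GoAnnotationSet:
    """Gene <-> term mappings closed under DAG ancestry."""

    gene2terms: dict[str, frozenset]
    term2genes: dict[str, frozenset]
    dag: nx.DiGraph
    names: dict[str, str] = field(default_factory=dict)


def propagate_annotations(
    direct: dict[str, set] | pd.DataFrame,
    dag_edges: pd.DataFrame,
    names: pd.DataFrame | None = None,
) -> GoAnnotationSet:
    """Close gene annotations under term ancestry (child -> parent edges).

    ``direct`` maps gene -> set of terms, or is a (gene_id, term_id)
    DataFrame.  Idempotent; a cycle in the edges raises with an example
    cycle.
    """
    if isinstance(direct, pd.DataFrame):
        mapping: dict[str, set] = {}
        for g, t in zip(direct.iloc[:, 0], direct.iloc[:, 1]):
            mapping.setdefault(str(g), set()).add(str(t))
        direct = mapping
    g = nx.DiGraph()
    g.add_edges_from(zip(dag_edges.iloc[:, 0].astype(str), dag_edges.iloc[:, 1].astype(str)))
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise AnalysisError(f"term graph contains a cycle: {cycle}")
    ancestors = {t: frozenset(nx.descendants(g, t)) for t in g.nodes}
    gene2terms = {}
    for gene, terms in direct.items():
        closed = set()
        for t in terms:
            closed.add(t)
            closed |= ancestors.get(t, frozenset())
        gene2terms[gene] = frozenset(closed)
    term2genes: dict[str, set] = {}
    for gene, terms in gene2terms.items():
        for t in terms:
            term2genes.setdefault(t, set()).add(gene)
    name_map = {}
    if names is not None:
        name_map = dict(zip(names.iloc[:, 0].astype(str), names.iloc[:, 1].astype(str)))
    return GoAnnotationSet(
        gene2terms=gene2terms,
        term2genes={t: frozenset(gs) for t, gs in term2genes.items()},
        dag=g,
        names=name_map,
    )


def hypergeom_test(
    set_genes,
    universe_genes,
    annotations: GoAnnotationSet,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over/under-representation per term.

    For each term with at least one annotated universe gene: with N universe
    genes, K of them annotated to the term, and a set of n genes containing k
    annotated ones, p_over = P[X >= k] and p_under = P[X <= k] (observed
    count included in both tails).  Direction flags use ``p_threshold``
    (uncorrected, per the reporting convention).
    """
    set_genes = set(set_genes)
    universe = set(universe_genes)
    if not set_genes or not universe:
        raise AnalysisError("gene set and universe must be non-empty")
    stray = sorted(set_genes - universe)
    if stray:
        raise AnalysisError(f"set genes not in universe: {', '.join(stray[:10])}")
    N, n = len(universe), len(set_genes)
    rows = []
    for term, genes in sorted(annotations.term2genes.items()):
        uni_genes = genes & universe
        K = len(uni_genes)
        if K == 0:
            continue
        k = len(uni_genes & set_genes)
        p_over = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_under = float(stats.hypergeom.cdf(k, N, K, n))
        rows.append(
            {
                "term_id": term,
                "term_name": annotations.names.get(term, ""),
                "set_count": k,
                "universe_count": K,
                "set_size": n,
                "universe_size": N,
                "p_over": p_over,
                "p_under": p_under,
                "over_represented": p_over < p_threshold,
                "under_represented": p_under < p_threshold,
            }
        )
    return pd.DataFrame(rows)


def highly_diverged_sets(
    mean_m_by_species: dict[str, pd.Series],
    feature_to_gene: pd.Series,
    fold: float = 4.0,
    pct_id_by_species: dict[str, pd.Series] | None = None,
) -> tuple[dict[str, set], set, pd.DataFrame]:
    """Per-species sets of genes with > ``fold``-fold hybridization reduction.

    A feature qualifies iff its mean M is strictly below -log2(fold); a gene
    is in a species' set if any of its features qualifies.  Returns the
    per-species gene sets, their intersection across all provided species,
    and a report table (gene, per-species %ID or NoHit) for the
    intersection.
    """
    if fold <= 1:
        raise ConfigurationError("fold must be > 1")
    cut = -np.log2(fold)
    sets: dict[str, set] = {}
    for sp, mean_m in mean_m_by_species.items():
        qual = mean_m[mean_m < cut].index
        sets[sp] = set(feature_to_gene.reindex(qual).dropna())
    species = list(sets)
    inter = set.intersection(*sets.values()) if sets else set()
    rows = []
    gene_features: dict[str, list] = {}
    for fid, gene in feature_to_gene.items():
        gene_features.setdefault(gene, []).append(fid)
    for gene in sorted(inter):
        row = {"gene_id": gene}
        for sp in species:
            val = NO_HIT
            if pct_id_by_species is not None and sp in pct_id_by_species:
                ids = pct_id_by_species[sp].reindex(gene_features.get(gene, []))
                ids = ids.dropna()
                if not ids.empty:
                    val = round(float(ids.min()), 2)
            row[f"pct_id_{sp}"] = val
        rows.append(row)
    table = pd.DataFrame(rows, columns=["gene_id"] + [f"pct_id_{sp}" for sp in species])
    return sets, inter, table
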