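"""Hybrid gene similarity (HGS) and the gene functional similarity matrix.

HGS follows Wang-style semantic-value propagation over a term's ancestor
subgraph, but instead of fixed per-relation weights it derives each edge
weight from the topology of the ontology itself:

    w = 1 / (numberOfChildren(t) + c) + d[relation]        (clipped at w_max)

A term with many children is less specific, so its contribution decays
faster.  The semantic value of the focus term X is 1; every ancestor t
receives

    S_X(t) = max over children t' of t inside DAG_X of  w(t'->t) * S_X(t')

and two terms are compared by the Wang aggregation over their shared
ancestors:

    sim(a, b) = sum_{t in T_a ∩ T_b} (S_a(t) + S_b(t)) / (SV(a) + SV(b)),
    SV(x) = sum_{t in T_x} S_x(t).

Gene-level similarity is the best-match average (BMA) over the two genes'
term sets, and :func:`build_gfs_matrix` assembles the symmetric, unit
diagonal gene x gene matrix whose rows double as classifier features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import AnnotationError
from .ontology import OntologyDAG, TermDAG, ancestor_dag, children_count

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HGSConfig:
    """Parameters of the hybrid edge weight.

    Parameters
    ----------
    c
        Additive constant in the weight denominator (> 0).  Larger c damps
        the influence of the children count.
    d
        Per-relation additive offset, each in [0, 1).  ``is_a`` edges carry
        a slightly larger offset than ``part_of`` by default.
    w_max
        Upper clip for the weight, in (0, 1); keeps every weight strictly
        below 1 so semantic values decay along the ancestor direction.
    weight_on
        Whose children count feeds the weight for an edge t' -> t:
        ``"child"`` uses t' (the term whose contribution is propagated,
        the default), ``"parent"`` uses t.
    """

    c: float = 2.0
    d: Mapping[str, float] = field(
        default_factory=lambda: {"is_a": 0.3, "part_of": 0.2}
    )
    w_max: float = 0.9
    weight_on: str = "child"

    def __post_init__(self):
        if not self.c > 0:
            raise ValueError(f"c must be positive, got {self.c}")
        for rel, off in self.d.items():
            if not (0.0 <= off < 1.0):
                raise ValueError(f"d[{rel!r}] must be in [0, 1), got {off}")
        if not (0.0 < self.w_max < 1.0):
            raise ValueError(f"w_max must be in (0, 1), got {self.w_max}")
        if self.weight_on not in ("child", "parent"):
            raise ValueError("weight_on must be 'child' or 'parent'")


@dataclass(frozen=True)
class SemanticValueTable:
    """Semantic values S_X(t) for every term t in the ancestor subgraph of
    the focus term X; ``values[X] == 1`` exactly."""

    focus: str
    values: Mapping[str, float]

    @property
    def sv(self) -> float:
        """SV(X): total semantic value over the ancestor subgraph."""
        return float(sum(self.values.values()))


@dataclass
class SimilarityMatrix:
    """Square symmetric gene x gene similarity matrix with unit diagonal."""

    gene_ids: Sequence[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} gene ids"
            )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.gene_ids)
        )


def edge_weight(n_children: int, relation: str, cfg: HGSConfig) -> float:
    """Hybrid edge weight ``min(w_max, 1/(n_children + c) + d[relation])``."""
    if n_children < 0:
        raise ValueError(f"n_children must be >= 0, got {n_children}")
    return min(cfg.w_max, 1.0 / (n_children + cfg.c) + cfg.d[relation])


def _propagate(termdag: TermDAG, weight):
    """Semantic values by max-product propagation from the focus outward.

    *weight* maps an edge triple ``(child, parent, relation)`` to its weight.
    Terms are processed in topological order (children before parents) so
    each value is final when read.
    """
    values: Dict[str, float] = {termdag.focus: 1.0}
    if len(termdag.termset) == 1:
        return values
    g = nx.DiGraph()
    g.add_nodes_from(termdag.termset)
    g.add_edges_from((c, p) for c, p, _r in termdag.edgeset)
    for t in nx.topological_sort(g):
        if t == termdag.focus:
            continue
        best = 0.0
        for c, _p, r in termdag.in_edges(t):
            if c in values:
                best = max(best, weight((c, t, r)) * values[c])
        values[t] = best
    return values


def semantic_values(dag: OntologyDAG, x: str, cfg: HGSConfig) -> SemanticValueTable:
    """Compute S_X(t) for every term t in the ancestor subgraph of *x*.

    The weight of an edge t' -> t uses the children count of t'
    (``cfg.weight_on == "child"``) or of t (``"parent"``), always counted on
    the full ontology, together with the edge's relation offset.
    """
    td = ancestor_dag(dag, x)

    def weight(edge):
        child, parent, rel = edge
        bearer = child if cfg.weight_on == "child" else parent
        return edge_weight(children_count(dag, bearer), rel, cfg)

    return SemanticValueTable(focus=x, values=_propagate(td, weight))


def term_similarity(dag: OntologyDAG, a: str, b: str, cfg: HGSConfig) -> float:
    """HGS similarity of two terms via shared-ancestor aggregation."""
    if a == b:
        dag._check(a)
        return 1.0
    ta = semantic_values(dag, a, cfg)
    tb = semantic_values(dag, b, cfg)
    return _aggregate(ta, tb)


def _aggregate(ta: SemanticValueTable, tb: SemanticValueTable) -> float:
    shared = ta.values.keys() & tb.values.keys()
    if not shared:
        return 0.0
    num = sum(ta.values[t] + tb.values[t] for t in shared)
    return float(num / (ta.sv + tb.sv))


def _bma(sim_grid: np.ndarray) -> float:
    """Best-match average of an m x n grid of term-pair similarities."""
    m, n = sim_grid.shape
    return float((sim_grid.max(axis=1).sum() + sim_grid.max(axis=0).sum()) / (m + n))


def gene_similarity(
    dag: OntologyDAG,
    terms1: Iterable[str],
    terms2: Iterable[str],
    cfg: HGSConfig,
    _cache: Optional[dict] = None,
    _tables: Optional[dict] = None,
) -> float:
    """Best-match-average similarity of two genes' term sets.

    BMA = [ sum_i max_j sim(t1_i, t2_j) + sum_j max_i sim(t1_i, t2_j) ]
          / (m + n).
    """
    t1 = sorted(set(terms1))
    t2 = sorted(set(terms2))
    if not t1 or not t2:
        raise AnnotationError("gene has an empty annotation term set")
    grid = np.empty((len(t1), len(t2)))
    for i, a in enumerate(t1):
        for j, b in enumerate(t2):
            grid[i, j] = _pair_sim(dag, a, b, cfg, _cache, _tables)
    return _bma(grid)


def _pair_sim(dag, a, b, cfg, cache, tables):
    if a == b:
        return 1.0
    if cache is None:
        return term_similarity(dag, a, b, cfg)
    key = (a, b) if a <= b else (b, a)
    if key not in cache:
        cache[key] = _aggregate(_table(dag, a, cfg, tables), _table(dag, b, cfg, tables))
    return cache[key]


def _table(dag, t, cfg, tables):
    if tables is None:
        return semantic_values(dag, t, cfg)
    if t not in tables:
        tables[t] = semantic_values(dag, t, cfg)
    return tables[t]


def build_gfs_matrix(
    dag: OntologyDAG,
    annotations: Mapping[str, Iterable[str]],
    cfg: Optional[HGSConfig] = None,
    drop_unannotated: bool = False,
) -> SimilarityMatrix:
    """Gene functional similarity matrix over all gene pairs.

    *annotations* maps gene id -> set of ontology term ids; terms absent
    from *dag* are ignored.  Genes left with no in-DAG terms raise
    :class:`AnnotationError` listing the offenders, unless
    *drop_unannotated* downgrades this to a logged warning.  Term-pair
    similarities are cached so each unordered pair is computed once; row
    order equals input gene order.
    """
    cfg = cfg or HGSConfig()
    genes = []
    termsets = []
    missing = []
    for gene, terms in annotations.items():
        usable = sorted(t for t in set(terms) if t in dag)
        if not usable:
            missing.append(gene)
        else:
            genes.append(gene)
            termsets.append(usable)
    if missing:
        if drop_unannotated:
            logger.warning(
                "dropping %d gene(s) with no in-DAG annotations: %s",
                len(missing), ", ".join(missing),
            )
        else:
            raise AnnotationError(
                "genes with no in-DAG annotations: " + ", ".join(missing)
            )

    n = len(genes)
    cache: dict = {}
    tables: dict = {}
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = gene_similarity(
                dag, termsets[i], termsets[j], cfg, _cache=cache, _tables=tables
            )
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(gene_ids=genes, values=values)
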