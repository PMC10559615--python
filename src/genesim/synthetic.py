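"""Synthetic fixtures: random ontology DAGs, class-structured gene
annotation cohorts with a planted similarity signal, and imbalanced
Gaussian-blob datasets.

The DAG generator emulates the biological-process branch of a gene
ontology: a single root, layered so that every non-root term's parents sit
in the immediately shallower layer (acyclic by construction), edges tagged
``is_a`` or ``part_of``.  The cohort generator plants a class signal the
similarity-based classifier can exploit: positive genes draw a fraction of
their annotation terms from the leaf pool of one designated "disease"
subtree, negatives draw from a disjoint background subtree.  All generators
are pure functions of their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Set, Tuple

import numpy as np

from .errors import SpecError
from .ontology import OntologyDAG, ancestor_dag
from .resampling import LabeledDataset


@dataclass(frozen=True)
class SyntheticDagSpec:
    """Shape of a random layered term DAG.

    Layer sizes grow geometrically toward the leaves (fan-out like a real
    ontology); each non-root term has 1..max_parents parents in the
    previous layer and each edge is ``part_of`` with probability
    ``part_of_fraction``, else ``is_a``.
    """

    n_terms: int = 300
    n_layers: int = 6
    max_parents: int = 2
    part_of_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (self.n_terms >= self.n_layers >= 1):
            raise SpecError("need n_terms >= n_layers >= 1")
        if self.max_parents < 1:
            raise SpecError("max_parents must be >= 1")
        if not (0.0 <= self.part_of_fraction <= 1.0):
            raise SpecError("part_of_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """A labelled gene cohort with a planted annotation signal.

    ``signal`` is the fraction of each positive gene's terms drawn from the
    disease leaf pool (rounded up); the rest, and all negative genes' terms,
    come from the background pool.
    """

    n_positive: int = 40
    n_negative: int = 160
    terms_per_gene: int = 8
    signal: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_positive < 2 or self.n_negative < 2:
            raise SpecError("need at least 2 genes per class")
        if self.terms_per_gene < 1:
            raise SpecError("terms_per_gene must be >= 1")
        if not (0.0 <= self.signal <= 1.0):
            raise SpecError("signal must be in [0, 1]")


def _layer_sizes(n_terms: int, n_layers: int) -> list:
    if n_layers == 1:
        return [n_terms]
    weights = np.array([2.0 ** i for i in range(n_layers - 1)])
    rest = n_terms - 1
    sizes = np.maximum(1, np.floor(rest * weights / weights.sum()).astype(int))
    # distribute the remainder into the deepest layers
    i = len(sizes) - 1
    while sizes.sum() < rest:
        sizes[i] += 1
        i = (i - 1) % len(sizes)
    while sizes.sum() > rest:
        j = int(np.argmax(sizes))
        sizes[j] -= 1
    # keep the root fanned out (real ontology roots have many children)
    want = min(3, rest - (len(sizes) - 1))
    while sizes[0] < want:
        j = int(np.argmax(sizes))
        sizes[j] -= 1
        sizes[0] += 1
    return [1] + sizes.tolist()


def synth_dag(spec: SyntheticDagSpec) -> OntologyDAG:
    """Generate a single-root layered DAG, acyclic by construction."""
    rng = np.random.default_rng(spec.seed)
    sizes = _layer_sizes(spec.n_terms, spec.n_layers)
    width = len(str(spec.n_terms))
    layers = []
    counter = 0
    for size in sizes:
        layers.append([f"SYN:{counter + i:0{width}d}" for i in range(size)])
        counter += size
    terms = [t for layer in layers for t in layer]

    edges = set()
    for li in range(1, len(layers)):
        parents_pool = layers[li - 1]
        for term in layers[li]:
            # skew toward single-parent terms, as in real ontologies
            n_par = 1
            while n_par < min(spec.max_parents, len(parents_pool)) and rng.uniform() < 0.3:
                n_par += 1
            chosen = rng.choice(len(parents_pool), size=n_par, replace=False)
            for pi in np.sort(chosen):
                rel = "part_of" if rng.uniform() < spec.part_of_fraction else "is_a"
                edges.add((term, parents_pool[pi], rel))

    return OntologyDAG(
        terms=frozenset(terms),
        edges=frozenset(edges),
        namespace={t: "biological_process" for t in terms},
        name={t: f"synthetic term {t}" for t in terms},
    )


def _leaf_pools(dag: OntologyDAG) -> Tuple[list, list]:
    """Disjoint disease/background leaf pools.

    Every leaf is assigned to one primary root-child subtree (the first of
    its root-child ancestors with the fewest leaves so far); subtrees are
    then split
    greedily into two sides with balanced leaf counts.  The disease pool is
    one side's leaves, the background pool the other's — disjoint by
    construction."""
    roots = sorted(dag.roots())
    if not roots:
        raise SpecError("DAG has no root")
    root_children = sorted(dag.children_of(roots[0]))
    if len(root_children) < 2:
        raise SpecError("DAG root needs at least 2 children for a cohort")

    leaves = sorted(dag.leaves())
    ancestor_sets = {leaf: ancestor_dag(dag, leaf).termset for leaf in leaves}

    def partition(anchors):
        assigned: Dict[str, list] = {a: [] for a in anchors}
        for leaf in leaves:
            owners = [a for a in anchors if a in ancestor_sets[leaf]]
            if owners:
                # spread shared leaves: give the leaf to its least-loaded owner
                target = min(owners, key=lambda a: (len(assigned[a]), a))
                assigned[target].append(leaf)
        return assigned

    anchors = set(root_children)
    assigned = partition(anchors)
    # if one subtree dominates, refine it into its children until a
    # balanced two-way split is possible
    for _ in range(10):
        dominant = max(assigned, key=lambda a: (len(assigned[a]), a))
        others = sum(len(v) for a, v in assigned.items() if a != dominant)
        if len(assigned[dominant]) <= others or not dag.children_of(dominant):
            break
        anchors = (anchors - {dominant}) | set(dag.children_of(dominant))
        assigned = partition(anchors)

    # greedy balanced split of subtree units into two sides
    sides: Tuple[list, list] = ([], [])
    for anchor in sorted(assigned, key=lambda a: (-len(assigned[a]), a)):
        side = 0 if len(sides[0]) <= len(sides[1]) else 1
        sides[side].extend(assigned[anchor])
    disease, background = sorted(sides[0]), sorted(sides[1])
    if not disease or not background:
        raise SpecError("could not form two non-empty leaf pools")
    return disease, background


def synth_cohort(dag: OntologyDAG, spec: SyntheticCohortSpec):
    """Generate gene annotations + labels with a planted similarity signal.

    Returns ``(annotations, labels)``: gene id -> term set, and gene id ->
    1 (positive) or 0 (negative).  Positive genes draw
    ``ceil(signal * terms_per_gene)`` terms from the disease leaf pool and
    the rest from the background pool; negatives draw only from background.
    """
    rng = np.random.default_rng(spec.seed)
    disease, background = _leaf_pools(dag)
    n_disease_terms = math.ceil(spec.signal * spec.terms_per_gene)
    n_background_terms = spec.terms_per_gene - n_disease_terms
    if len(disease) < n_disease_terms:
        raise SpecError(
            f"disease leaf pool has {len(disease)} terms, "
            f"need {n_disease_terms} per positive gene"
        )
    if len(background) < spec.terms_per_gene:
        raise SpecError(
            f"background leaf pool has {len(background)} terms, "
            f"need {spec.terms_per_gene} per gene"
        )

    annotations: Dict[str, Set[str]] = {}
    labels: Dict[str, int] = {}
    for i in range(spec.n_positive):
        gene = f"POS{i:04d}"
        picked = set(rng.choice(disease, size=n_disease_terms, replace=False))
        if n_background_terms:
            picked |= set(rng.choice(background, size=n_background_terms, replace=False))
        annotations[gene] = picked
        labels[gene] = 1
    for i in range(spec.n_negative):
        gene = f"NEG{i:04d}"
        annotations[gene] = set(
            rng.choice(background, size=spec.terms_per_gene, replace=False)
        )
        labels[gene] = 0
    return annotations, labels


def synth_blobs(
    n_majority: int, n_minority: int, dim: int = 2,
    separation: float = 6.0, seed: int = 0,
) -> LabeledDataset:
    """Two spherical unit-variance Gaussian clusters with centres
    *separation* apart; the minority cluster is the positive class."""
    if n_majority < 2 or n_minority < 2:
        raise SpecError("need at least 2 samples per class")
    if dim < 1 or separation < 0:
        raise SpecError("dim must be >= 1 and separation >= 0")
    rng = np.random.default_rng(seed)
    offset = np.zeros(dim)
    offset[0] = separation
    x_maj = rng.standard_normal((n_majority, dim))
    x_min = rng.standard_normal((n_minority, dim)) + offset
    features = np.vstack([x_maj, x_min])
    labels = np.concatenate([np.zeros(n_majority, int), np.ones(n_minority, int)])
    ids = [f"maj{i:05d}" for i in range(n_majority)] + [
        f"min{i:05d}" for i in range(n_minority)
    ]
    return LabeledDataset(features=features, labels=labels, sample_ids=ids)


def write_obo(dag: OntologyDAG, path) -> None:
    """Write the minimal OBO stanza set the reader consumes
    (id/name/namespace/is_a/relationship), making DAG round-trips exact."""
    parents: Dict[str, list] = {t: [] for t in dag.terms}
    for child, parent, rel in sorted(dag.edges):
        parents[child].append((parent, rel))
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.name.get(term, term)}\n")
            ns = dag.namespace.get(term)
            if ns:
                fh.write(f"namespace: {ns}\n")
            for parent, rel in parents[term]:
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
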