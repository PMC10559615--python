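"""Shared fixtures: tiny hand-built DAGs and OBO texts, separable blobs."""

import numpy as np
import pytest

from genesim.ontology import OntologyDAG
from genesim.semsim import HGSConfig
from genesim.synthetic import synth_blobs

BP = "biological_process"


def make_dag(edges, extra_terms=()):
    terms = set(extra_terms)
    for c, p, _r in edges:
        terms |= {c, p}
    return OntologyDAG(
        terms=frozenset(terms),
        edges=frozenset(edges),
        namespace={t: BP for t in terms},
    )


@pytest.fixture
def chain_dag():
    """C -> B -> A (is_a)."""
    return make_dag([("C", "B", "is_a"), ("B", "A", "is_a")])


@pytest.fixture
def diamond_dag():
    """D -> {B, C} -> A."""
    return make_dag(
        [("D", "B", "is_a"), ("D", "C", "is_a"),
         ("B", "A", "is_a"), ("C", "A", "is_a")]
    )


@pytest.fixture
def chain_w05_cfg():
    """On the chain DAG every edge's parent has exactly one child, so
    weight_on='parent' with c=2, d=1/6 gives a uniform weight of 0.5."""
    return HGSConfig(c=2.0, d={"is_a": 1.0 / 6.0}, w_max=0.9, weight_on="parent")


@pytest.fixture
def separable_blobs():
    """200 samples, 6-sigma separation: linearly separable with margin."""
    return synth_blobs(n_majority=150, n_minority=50, dim=2, separation=6.0, seed=0)


@pytest.fixture
def overlap_blobs():
    """200 samples, moderate separation: learnable but not trivially."""
    return synth_blobs(n_majority=150, n_minority=50, dim=5, separation=2.0, seed=0)


MINI_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: child process
namespace: biological_process
is_a: GO:0000001
"""

MINI_OBO_OBSOLETE = """format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: dead process
namespace: biological_process
is_a: GO:0000001
is_obsolete: true
"""

MINI_OBO_MIXED_NS = """format-version: 1.2

[Term]
id: GO:0000001
name: bp root
namespace: biological_process

[Term]
id: GO:0000002
name: bp child
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: mf root
namespace: molecular_function

[Term]
id: GO:0000004
name: mf child
namespace: molecular_function
is_a: GO:0000003
"""

MINI_OBO_PARTOF = """format-version: 1.2

[Term]
id: GO:0000001
name: whole
namespace: biological_process

[Term]
id: GO:0000002
name: part
namespace: biological_process
relationship: part_of GO:0000001

[Term]
id: GO:0000003
name: regulator
namespace: biological_process
relationship: regulates GO:0000001
"""


@pytest.fixture
def obo_file(tmp_path):
    def _write(text, name="mini.obo"):
        path = tmp_path / name
        path.write_text(text)
        return str(path)

    return _write
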