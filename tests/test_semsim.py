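"""HGS edge weights, semantic-value propagation, term and gene similarity."""

import numpy as np
import pytest

from genesim.errors import AnnotationError
from genesim.ontology import ancestor_dag
from genesim.semsim import (
    HGSConfig,
    _bma,
    _propagate,
    build_gfs_matrix,
    edge_weight,
    gene_similarity,
    semantic_values,
    term_similarity,
)
from genesim.synthetic import SyntheticCohortSpec, SyntheticDagSpec, synth_cohort, synth_dag

from conftest import make_dag


class TestEdgeWeight:
    def test_direct_evaluation(self):
        cfg = HGSConfig(c=2.0, d={"is_a": 0.3})
        assert edge_weight(3, "is_a", cfg) == pytest.approx(0.5, abs=1e-12)

    def test_leaf_children(self):
        cfg = HGSConfig(c=2.0, d={"is_a": 0.3}, w_max=0.9)
        assert edge_weight(0, "is_a", cfg) == pytest.approx(0.8, abs=1e-12)

    def test_clip_branch(self):
        cfg = HGSConfig(c=1.0, d={"is_a": 0.3}, w_max=0.9)
        assert edge_weight(0, "is_a", cfg) == pytest.approx(0.9, abs=1e-12)

    def test_negative_children_rejected(self):
        with pytest.raises(ValueError):
            edge_weight(-1, "is_a", HGSConfig())

    @pytest.mark.parametrize(
        "kwargs", [{"c": 0.0}, {"d": {"is_a": 1.0}}, {"w_max": 1.0},
                   {"w_max": 0.0}, {"weight_on": "edge"}]
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            HGSConfig(**kwargs)


class TestSemanticValues:
    def test_chain_uniform_half(self, chain_dag, chain_w05_cfg):
        table = semantic_values(chain_dag, "C", chain_w05_cfg)
        assert table.values == pytest.approx({"C": 1.0, "B": 0.5, "A": 0.25})

    def test_root_identity(self, chain_dag, chain_w05_cfg):
        table = semantic_values(chain_dag, "A", chain_w05_cfg)
        assert table.values == {"A": 1.0}

    def test_diamond_max_over_paths(self, diamond_dag):
        """S_D(A) takes the best path: max(0.5*0.5, 0.8*0.5) = 0.4."""
        weights = {
            ("D", "B", "is_a"): 0.5,
            ("D", "C", "is_a"): 0.8,
            ("B", "A", "is_a"): 0.5,
            ("C", "A", "is_a"): 0.5,
        }
        td = ancestor_dag(diamond_dag, "D")
        values = _propagate(td, weights.__getitem__)
        assert values == pytest.approx({"D": 1.0, "B": 0.5, "C": 0.8, "A": 0.4})

    def test_focus_value_is_one_and_decay(self):
        dag = synth_dag(SyntheticDagSpec(n_terms=50, seed=7))
        cfg = HGSConfig()
        for t in sorted(dag.terms)[::10]:
            table = semantic_values(dag, t, cfg)
            assert table.values[t] == 1.0
            assert all(0.0 < v <= 1.0 for v in table.values.values())


class TestTermSimilarity:
    def test_self_similarity(self, chain_dag, chain_w05_cfg):
        assert term_similarity(chain_dag, "B", "B", chain_w05_cfg) == pytest.approx(1.0)

    def test_disjoint_components(self, chain_w05_cfg):
        dag = make_dag([("B", "A", "is_a"), ("Y", "X", "is_a")])
        assert term_similarity(dag, "B", "Y", chain_w05_cfg) == 0.0

    def test_chain_worked_example(self, chain_dag, chain_w05_cfg):
        """sim(C, B) = (0.5+1 + 0.25+0.5) / (1.75+1.5) = 2.25/3.25."""
        sim = term_similarity(chain_dag, "C", "B", chain_w05_cfg)
        assert sim == pytest.approx(2.25 / 3.25, abs=1e-12)

    def test_symmetry(self, chain_dag, chain_w05_cfg):
        ab = term_similarity(chain_dag, "C", "A", chain_w05_cfg)
        ba = term_similarity(chain_dag, "A", "C", chain_w05_cfg)
        assert ab == pytest.approx(ba, abs=1e-12)


class TestGeneSimilarity:
    def test_identical_sets(self, chain_dag, chain_w05_cfg):
        assert gene_similarity(chain_dag, {"C", "B"}, {"C", "B"}, chain_w05_cfg) == 1.0

    def test_single_pair_bma(self):
        assert _bma(np.array([[0.4]])) == pytest.approx(0.4)

    def test_two_by_one_bma(self):
        # terms1={a,b}, terms2={b}, sim(a,b)=0.4:
        # (max(0.4) + max(1.0) + max(0.4, 1.0)) / 3 = 0.8
        grid = np.array([[0.4], [1.0]])
        assert _bma(grid) == pytest.approx(0.8)

    def test_bma_from_dag(self, chain_dag, chain_w05_cfg):
        s_cb = term_similarity(chain_dag, "C", "B", chain_w05_cfg)
        expected = (s_cb + 1.0 + 1.0) / 3.0
        got = gene_similarity(chain_dag, {"C", "B"}, {"B"}, chain_w05_cfg)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_set_rejected(self, chain_dag, chain_w05_cfg):
        with pytest.raises(AnnotationError):
            gene_similarity(chain_dag, set(), {"B"}, chain_w05_cfg)

    def test_monotone_dilution(self, chain_w05_cfg):
        """Adding a zero-similarity term strictly decreases the BMA."""
        dag = make_dag(
            [("C", "B", "is_a"), ("B", "A", "is_a"), ("Y", "X", "is_a")]
        )
        base = gene_similarity(dag, {"C", "B"}, {"B"}, chain_w05_cfg)
        diluted = gene_similarity(dag, {"C", "B"}, {"B", "Y"}, chain_w05_cfg)
        assert diluted < base


class TestGfsMatrix:
    def test_single_gene(self, chain_dag, chain_w05_cfg):
        m = build_gfs_matrix(chain_dag, {"g1": {"C"}}, chain_w05_cfg)
        assert m.values.tolist() == [[1.0]]

    def test_identical_genes(self, chain_dag, chain_w05_cfg):
        m = build_gfs_matrix(
            chain_dag, {"g1": {"C", "B"}, "g2": {"C", "B"}}, chain_w05_cfg
        )
        assert np.allclose(m.values, 1.0)

    def test_matches_cache_free_recomputation(self, chain_dag, chain_w05_cfg):
        ann = {"g1": {"C"}, "g2": {"B"}, "g3": {"C", "A"}}
        m = build_gfs_matrix(chain_dag, ann, chain_w05_cfg)
        genes = list(ann)
        for i, gi in enumerate(genes):
            for j, gj in enumerate(genes):
                expected = (
                    1.0 if i == j
                    else gene_similarity(chain_dag, ann[gi], ann[gj], chain_w05_cfg)
                )
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_unannotated_gene_rejected_and_listed(self, chain_dag, chain_w05_cfg):
        with pytest.raises(AnnotationError, match="ghost"):
            build_gfs_matrix(
                chain_dag, {"g1": {"C"}, "ghost": {"NOPE"}}, chain_w05_cfg
            )

    def test_drop_unannotated_flag(self, chain_dag, chain_w05_cfg):
        m = build_gfs_matrix(
            chain_dag, {"g1": {"C"}, "ghost": {"NOPE"}}, chain_w05_cfg,
            drop_unannotated=True,
        )
        assert m.gene_ids == ["g1"]

    def test_invariants_on_random_annotation_sets(self):
        for seed in range(20):
            dag = synth_dag(SyntheticDagSpec(n_terms=60, seed=seed))
            ann, _labels = synth_cohort(
                dag,
                SyntheticCohortSpec(
                    n_positive=3, n_negative=5, terms_per_gene=3, seed=seed
                ),
            )
            m = build_gfs_matrix(dag, ann)
            assert np.allclose(m.values, m.values.T, atol=1e-12)
            assert np.allclose(np.diag(m.values), 1.0)
            assert m.values.min() >= 0.0 and m.values.max() <= 1.0


def _wang_fixed_weight(dag, focus, w):
    """Independent Wang-style oracle: semantic values with one fixed weight,
    computed by fixed-point relaxation rather than topological order."""
    termset = ancestor_dag(dag, focus).termset
    values = {focus: 1.0}
    changed = True
    while changed:
        changed = False
        for t in termset:
            if t == focus:
                continue
            candidates = [
                w * values[c]
                for c in dag.children_of(t)
                if c in termset and c in values
            ]
            if candidates:
                new = max(candidates)
                if abs(values.get(t, -1.0) - new) > 1e-15:
                    values[t] = new
                    changed = True
    return values


class TestWangEquivalence:
    def test_uniform_fanout_matches_fixed_weight_wang(self):
        """On a 3-ary tree every internal term has 3 children, so with
        weight_on='parent', c=2, d=0.6 every traversed edge weighs
        1/(3+2)+0.6 = 0.8 and HGS must reduce to fixed-weight Wang."""
        edges = []
        nodes = ["n0"]
        frontier = ["n0"]
        counter = 1
        for _depth in range(3):
            nxt = []
            for parent in frontier:
                for _ in range(3):
                    child = f"n{counter}"
                    counter += 1
                    edges.append((child, parent, "is_a"))
                    nodes.append(child)
                    nxt.append(child)
            frontier = nxt
        dag = make_dag(edges)
        cfg = HGSConfig(c=2.0, d={"is_a": 0.6}, w_max=0.9, weight_on="parent")

        rng = np.random.default_rng(42)
        terms = sorted(dag.terms)
        for _ in range(50):
            a, b = (terms[i] for i in rng.integers(len(terms), size=2))
            sa = _wang_fixed_weight(dag, a, 0.8)
            sb = _wang_fixed_weight(dag, b, 0.8)
            shared = sa.keys() & sb.keys()
            expected = (
                sum(sa[t] + sb[t] for t in shared)
                / (sum(sa.values()) + sum(sb.values()))
                if shared
                else 0.0
            )
            assert term_similarity(dag, a, b, cfg) == pytest.approx(
                expected, abs=1e-9
            )
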