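"""Synthetic genomes, insertion libraries, interactomes and gene sets."""

import numpy as np
import pytest

from traprescue import (
    InteractomeSpec,
    SimulationConfig,
    generate_annotation,
    generate_gene_sets,
    generate_interactome,
    generate_screen_pair,
    generate_screen_set,
)
from traprescue.annotate import InsertionClass, classify_library


class TestGenerateAnnotation:
    def test_construction_contract(self):
        genes = generate_annotation(SimulationConfig(n_genes=10, seed=1))
        assert len(genes) == 10
        for g in genes:
            assert g.start < g.end
            assert g.exons[0][0] == g.start and g.exons[-1][1] == g.end
            for s, e in g.exons:
                assert g.start <= s < e <= g.end
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # non-overlapping

    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(n_genes=25, seed=3)
        assert generate_annotation(cfg) == generate_annotation(cfg)

    def test_single_exon_genes_have_no_introns(self):
        cfg = SimulationConfig(n_genes=10, exons_per_gene=(1, 1), seed=2)
        for g in generate_annotation(cfg):
            assert g.exons == ((g.start, g.end),)

    def test_strands_roughly_balanced(self):
        genes = generate_annotation(SimulationConfig(n_genes=200, seed=4))
        plus = sum(g.strand == "+" for g in genes)
        assert 60 <= plus <= 140

    def test_infeasible_chromosome_rejected(self):
        cfg = SimulationConfig(n_genes=10, seed=1)
        with pytest.raises(ValueError, match="cannot hold"):
            generate_annotation(cfg, chrom_length=100)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimulationConfig(enrichment_factor=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(intergenic_fraction=1.0)


class TestGenerateScreenPair:
    def test_planted_share_matches_intensity_model(self):
        """One gene boosted λ=50 among 100 equal-length genes should draw
        about 50/(99+50) of the genic insertions."""
        cfg = SimulationConfig(
            n_genes=100,
            gene_length_range=(5000, 5000),
            n_control_insertions=1000,
            n_selected_insertions=40_000,
            planted_genes=("G0050",),
            enrichment_factor=50.0,
            intergenic_fraction=0.0,
            seed=5,
        )
        ann = generate_annotation(cfg)
        _, selected, truth = generate_screen_pair(ann, cfg)
        planted_gene = next(g for g in ann if g.gene_id == "G0050")
        n_in = sum(planted_gene.contains(i.pos) for i in selected)
        expected = 50 / 149
        sd = np.sqrt(expected * (1 - expected) / len(selected))
        assert abs(n_in / len(selected) - expected) < 4 * sd
        assert truth == {"planted_genes": ["G0050"], "enrichment_factor": 50.0}

    def test_lambda_one_is_the_null(self):
        """With λ=1 the selected library follows the control distribution:
        per-gene insertion fractions agree within binomial noise."""
        cfg = SimulationConfig(
            n_genes=50,
            n_control_insertions=30_000,
            n_selected_insertions=30_000,
            planted_genes=("G0001",),
            enrichment_factor=1.0,
            seed=6,
        )
        ann = generate_annotation(cfg)
        control, selected, _ = generate_screen_pair(ann, cfg)
        g1 = ann[0]
        f_ctl = sum(g1.contains(i.pos) for i in control) / len(control)
        f_sel = sum(g1.contains(i.pos) for i in selected) / len(selected)
        sd = np.sqrt(2 * f_ctl * (1 - f_ctl) / 30_000)
        assert abs(f_ctl - f_sel) < 5 * sd

    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(n_genes=20, n_control_insertions=500,
                               n_selected_insertions=500, seed=7)
        ann = generate_annotation(cfg)
        assert generate_screen_pair(ann, cfg) == generate_screen_pair(ann, cfg)

    def test_unknown_planted_gene_rejected(self):
        cfg = SimulationConfig(n_genes=5, planted_genes=("NOPE",), seed=1)
        ann = generate_annotation(cfg)
        with pytest.raises(KeyError, match="NOPE"):
            generate_screen_pair(ann, cfg)

    def test_intergenic_fraction_realised(self):
        cfg = SimulationConfig(
            n_genes=50, n_control_insertions=20_000,
            n_selected_insertions=100, intergenic_fraction=0.2, seed=8,
        )
        ann = generate_annotation(cfg)
        control, _, _ = generate_screen_pair(ann, cfg)
        frac = np.mean(
            [r.klass is InsertionClass.INTERGENIC
             for r in classify_library(control, ann)]
        )
        assert abs(frac - 0.2) < 0.02


def test_generate_screen_set_shared_and_private_planting():
    cfg = SimulationConfig(
        n_genes=30, n_backgrounds=3, shared_planted=("G0001", "G0002"),
        n_control_insertions=200, n_selected_insertions=200, seed=9,
    )
    ann = generate_annotation(cfg)
    control, selected, truth = generate_screen_set(
        ann, cfg, private_planted={"bg2": ["G0010"]}
    )
    assert set(selected) == {"bg1", "bg2", "bg3"}
    assert truth["planted_by_background"]["bg2"] == ["G0001", "G0002", "G0010"]
    assert truth["planted_by_background"]["bg1"] == ["G0001", "G0002"]
    assert all(i.library == "control" for i in control)


class TestGenerateInteractome:
    def test_deterministic_limit_two_triangles(self):
        spec = InteractomeSpec(
            communities=(("a", "b", "c"), ("d", "e", "f")), p_in=1.0, p_out=0.0
        )
        g = generate_interactome(spec)
        assert g.number_of_edges() == 6
        comps = {frozenset(c) for c in __import__("networkx").connected_components(g)}
        assert comps == {frozenset("abc"), frozenset("def")}

    def test_within_block_density_close_to_p_in(self):
        blocks = tuple(tuple(f"b{b}n{i}" for i in range(50)) for b in range(2))
        g = generate_interactome(
            InteractomeSpec(communities=blocks, p_in=0.9, p_out=0.05, seed=10)
        )
        n_pairs = 50 * 49 // 2
        for block in blocks:
            within = sum(
                g.has_edge(u, v)
                for i, u in enumerate(block)
                for v in block[i + 1 :]
            )
            sd = np.sqrt(0.9 * 0.1 / n_pairs)
            assert abs(within / n_pairs - 0.9) < 3 * sd

    def test_simple_graph_invariants(self):
        blocks = (tuple(f"n{i}" for i in range(30)),)
        g = generate_interactome(
            InteractomeSpec(communities=blocks, p_in=0.3, p_out=0.0, seed=11)
        )
        assert not any(u == v for u, v in g.edges)

    def test_deterministic_under_fixed_seed(self):
        spec = InteractomeSpec(
            communities=(tuple(f"n{i}" for i in range(20)),), p_in=0.4,
            p_out=0.0, seed=12,
        )
        g1, g2 = generate_interactome(spec), generate_interactome(spec)
        assert sorted(g1.edges) == sorted(g2.edges)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            InteractomeSpec(communities=(("a",), ("a",)), p_in=0.5, p_out=0.1)
        with pytest.raises(ValueError):
            InteractomeSpec(communities=(("a",),), p_in=0.2, p_out=0.5)


class TestGenerateGeneSets:
    def test_community_blocks_become_sets(self):
        ids = [f"g{i}" for i in range(40)]
        sets = generate_gene_sets(ids, community_blocks=[ids[:10]], seed=13)
        assert sets["community_1"] == sorted(ids[:10])

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            generate_gene_sets(["a", "b"], community_blocks=[[]],
                               set_size_range=(1, 2))

    def test_deterministic_under_fixed_seed(self):
        ids = [f"g{i}" for i in range(40)]
        assert generate_gene_sets(ids, seed=14) == generate_gene_sets(ids, seed=14)

    def test_invalid_size_range_rejected(self):
        with pytest.raises(ValueError):
            generate_gene_sets(["a", "b"], set_size_range=(3, 5))
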