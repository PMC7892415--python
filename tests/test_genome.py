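"""Genome generation, rendering, mutation, and serialization."""

import numpy as np
import pytest

from evocamo.genome import (
    GeneNode,
    GenomeParseError,
    OPERATORS,
    mutate_genome,
    parse_genome,
    random_genome,
    render_genome,
    serialize_genome,
)


class TestRandomGenome:
    def test_depth_one_is_single_terminal(self):
        g = random_genome(seed=1, max_depth=1)
        assert g.depth == 1
        assert OPERATORS[g.root.op_name].arity == 0

    def test_respects_max_depth_and_arities(self):
        g = random_genome(seed=42, max_depth=8)
        assert g.depth <= 8
        for node in g.root.walk():
            assert len(node.children) == OPERATORS[node.op_name].arity
            assert all(np.isfinite(node.params))

    def test_seed_reproducibility(self):
        a, b = random_genome(7), random_genome(7)
        assert serialize_genome(a) == serialize_genome(b)
        assert a.genome_id == b.genome_id

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError, match="max_depth"):
            random_genome(0, max_depth=0)

    def test_population_spans_luminance_range(self):
        # Monte-Carlo: 512 random genomes produce both dark and bright
        # pixels, and every id is unique
        ids, lo, hi = set(), 255, 0
        for seed in range(512):
            g = random_genome(seed)
            ids.add(g.genome_id)
            img = render_genome(g)
            lo, hi = min(lo, int(img.min())), max(hi, int(img.max()))
        assert len(ids) == 512
        assert lo < 64 and hi > 191


class TestRender:
    def test_constant_is_uniform(self):
        img = render_genome(parse_genome("(const 127.0)"))
        assert img.shape == (100, 75)
        assert np.all(img == 127)

    def test_clamps_above_255(self):
        img = render_genome(parse_genome("(add (const 300.0) (const 300.0))"))
        assert np.all(img == 255)

    def test_clamps_below_0(self):
        img = render_genome(parse_genome("(subtract (const 0.0) (const 300.0))"))
        assert np.all(img == 0)

    def test_vertical_grating_closed_form(self):
        img = render_genome(
            parse_genome("(sine_warp (const 127.0) 0.0 10.0 0.0 127.0)")
        ).astype(float)
        # vertical stripes: each column constant, profile sinusoidal along x
        assert np.allclose(img.std(axis=0), 0)
        x = np.arange(75) + 0.5
        expected = np.clip(np.rint(127 + 127 * np.sin(2 * np.pi * x / 10.0)), 0, 255)
        assert np.allclose(img[0], expected)

    def test_render_is_pure(self):
        g = random_genome(3)
        assert np.array_equal(render_genome(g), render_genome(g))

    @pytest.mark.parametrize("seed", range(8))
    def test_output_always_in_range(self, seed):
        img = render_genome(random_genome(seed))
        assert img.dtype == np.uint8
        assert img.min() >= 0 and img.max() <= 255


class TestMutation:
    def test_rate_zero_is_phenotype_identity(self):
        g = random_genome(5)
        child = mutate_genome(g, np.random.default_rng(0), mutation_rate=0.0)
        assert child.genome_id != g.genome_id
        assert child.lineage == g.genome_id
        assert np.array_equal(render_genome(child), render_genome(g))

    def test_rate_one_jitter_only_keeps_structure(self):
        g = random_genome(9, max_depth=5)
        child = mutate_genome(g, np.random.default_rng(1), mutation_rate=1.0,
                              modes=("jitter",))
        assert child.depth == g.depth
        ops_parent = [n.op_name for n in g.root.walk()]
        ops_child = [n.op_name for n in child.root.walk()]
        assert ops_parent == ops_child
        # every parameterized node's params perturbed
        for np_, nc in zip(g.root.walk(), child.root.walk()):
            if np_.params:
                assert np_.params != nc.params

    def test_mutated_node_count_matches_binomial_expectation(self):
        # rate 0.05 on a 20-node genome: expect a binomial 20 * 0.05 = 1.0
        # mutated nodes per offspring.  Use a chain where every node carries
        # a parameter so each mutation event is observable.
        from evocamo.genome import PatternGenome

        node = GeneNode("const", [127.0], [])
        for i in range(19):
            node = GeneNode("threshold", [float(10 + i * 10) % 255], [node])
        g = PatternGenome(node, genome_id="chain20")
        assert g.root.n_nodes() == 20
        rng = np.random.default_rng(2)
        counts = []
        for _ in range(1000):
            child = mutate_genome(g, rng, mutation_rate=0.05, max_depth=20,
                                  modes=("jitter",))
            changed = sum(
                1
                for a, b in zip(g.root.walk(), child.root.walk())
                if a.params != b.params
            )
            counts.append(changed)
        assert np.mean(counts) == pytest.approx(1.0, abs=0.2)

    def test_depth_cap_enforced(self):
        g = random_genome(11, max_depth=8)
        rng = np.random.default_rng(3)
        for _ in range(50):
            g = mutate_genome(g, rng, mutation_rate=0.3, max_depth=8)
            assert g.depth <= 8


class TestSerialization:
    @pytest.mark.parametrize("seed", [7] + list(range(100)))
    def test_round_trip_renders_identically(self, seed):
        g = random_genome(seed)
        back = parse_genome(serialize_genome(g))
        assert np.array_equal(render_genome(back), render_genome(g))

    def test_empty_text_rejected(self):
        with pytest.raises(GenomeParseError, match="empty"):
            parse_genome("")

    def test_unknown_operator_named_in_error(self):
        with pytest.raises(GenomeParseError, match="frobnicate"):
            parse_genome("(frobnicate 1.0)")

    def test_arity_mismatch_rejected(self):
        with pytest.raises(GenomeParseError, match="children"):
            parse_genome("(add (const 1.0))")

    def test_trailing_tokens_rejected(self):
        with pytest.raises(GenomeParseError, match="trailing"):
            parse_genome("(const 1.0) (const 2.0)")


class TestGeneNode:
    def test_arity_invariant_enforced(self):
        with pytest.raises(ValueError, match="children"):
            GeneNode("add", [], [GeneNode("const", [1.0], [])])

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            GeneNode("const", [float("nan")], [])


class TestRenderInvariants:
    """Property: rendering never leaves [0, 255] and mutation never exceeds
    the depth cap, across arbitrary seeds."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 2**20))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_render_clamped_and_mutation_depth_capped(self, seed):
        g = random_genome(seed, max_depth=6)
        img = render_genome(g)
        assert img.min() >= 0 and img.max() <= 255
        child = mutate_genome(g, np.random.default_rng(seed), 0.2, max_depth=6)
        assert child.depth <= 6
        cimg = render_genome(child)
        assert cimg.min() >= 0 and cimg.max() <= 255
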