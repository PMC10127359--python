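"""Contrasts, signal randomization test, and contrast correlations."""
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import gls_contrast_sum_of_squares
from aridtrait.phylo import (
    PhyloError,
    contrast_variance,
    encode_nesting,
    independent_contrasts,
    pic_correlation,
    read_newick,
    signal_test,
)
from aridtrait.synthetic import simulate_bm_traits, simulate_tree


class TestReadNewick:
    def test_two_tip_tree(self):
        tree = read_newick("(A:1,B:1);")
        assert tree.n_tips == 2
        assert len(tree.internal_nodes) == 1
        assert sorted(tree.tip_labels) == ["A", "B"]

    def test_three_tip_path_lengths(self):
        tree = read_newick("((A:1,B:1):1,C:2);")

        def depth(label):
            total = {}

            def walk(node, acc):
                if node.length:
                    acc += node.length
                if node.is_tip:
                    total[node.label] = acc
                for c in node.children:
                    walk(c, acc)

            walk(tree.root, 0.0)
            return total[label]

        assert depth("A") == depth("B") == depth("C") == 2.0

    def test_polytomy_rejected(self):
        with pytest.raises(PhyloError, match="polytomy"):
            read_newick("(A:1,B:1,C:1);")

    def test_missing_branch_length_names_the_node(self):
        with pytest.raises(PhyloError, match="B"):
            read_newick("(A:1,B);")

    def test_zero_branch_length_rejected(self):
        with pytest.raises(PhyloError, match="non-positive"):
            read_newick("(A:0,B:1);")

    def test_roundtrip_through_newick(self):
        tree = simulate_tree(12, seed=5)
        again = read_newick(tree.to_newick())
        assert again.to_newick() == tree.to_newick()


class TestIndependentContrasts:
    def test_two_tip_formula(self):
        tree = read_newick("(A:1,B:1);")
        cs = independent_contrasts(tree, {"A": 3.0, "B": 1.0})
        assert cs.contrasts == pytest.approx([2 / np.sqrt(2)])

    def test_hand_computed_three_tip_example(self):
        # (A-B)/sqrt(2) = -sqrt(2); ancestor value 3, its branch extended
        # to 1 + 1*1/2 = 1.5, so (3-6)/sqrt(1.5+2)
        tree = read_newick("((A:1,B:1):1,C:2);")
        cs = independent_contrasts(tree, {"A": 2.0, "B": 4.0, "C": 6.0})
        assert sorted(cs.contrasts) == pytest.approx(
            sorted([-1.4142135, -3 / np.sqrt(3.5)]), abs=1e-6
        )
        assert cs.n_contrasts == 2

    def test_constant_trait_gives_zero_contrasts(self):
        tree = simulate_tree(10, seed=2)
        cs = independent_contrasts(tree, {t: 5.0 for t in tree.tip_labels})
        assert np.allclose(cs.contrasts, 0.0)
        assert np.all(cs.variances > 0)

    def test_missing_tip_listed(self):
        tree = read_newick("(A:1,B:1);")
        with pytest.raises(PhyloError, match="B"):
            independent_contrasts(tree, {"A": 1.0})

    def test_matches_brownian_gls_oracle(self):
        """Sum of squared contrasts equals the brute-force GLS quadratic form
        computed from the full Brownian covariance matrix."""
        for seed in range(50):
            tree = simulate_tree(3 + seed % 6, seed=seed)
            traits = simulate_bm_traits(tree, 1.3, 0.5, seed=seed + 1000)
            cs = independent_contrasts(tree, traits)
            ours = float(np.sum(cs.contrasts**2))
            oracle = gls_contrast_sum_of_squares(tree, traits)
            assert ours == pytest.approx(oracle, rel=1e-8)

    def test_matches_r_ape_pic(self, tmp_path):
        """Contrast values agree with R's ape::pic on a simulated tree."""
        tree = simulate_tree(8, seed=11)
        traits = simulate_bm_traits(tree, 2.0, 0.0, seed=12)
        cs = independent_contrasts(tree, traits)
        script = tmp_path / "pic.R"
        script.write_text(textwrap.dedent(f"""
            library(ape)
            tr <- read.tree(text='{tree.to_newick()}')
            x <- c({','.join(f'{traits[t]!r}' for t in tree.tip_labels)})
            names(x) <- c({','.join(f'"{t}"' for t in tree.tip_labels)})
            cat(sprintf('%.12f\\n', sort(abs(pic(x, tr)))))
        """))
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        )
        r_vals = np.array([float(v) for v in out.stdout.split()])
        assert np.sort(np.abs(cs.contrasts)) == pytest.approx(r_vals, rel=1e-9)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(n_tips=st.integers(2, 40), seed=st.integers(0, 10_000))
def test_contrast_count_conservation(n_tips, seed):
    tree = simulate_tree(n_tips, seed=seed)
    traits = simulate_bm_traits(tree, 1.0, 0.0, seed=seed + 1)
    cs = independent_contrasts(tree, traits)
    assert cs.n_contrasts == n_tips - 1


def test_contrast_variance_conventions():
    tree = read_newick("((A:1,B:1):1,C:2);")
    cs = independent_contrasts(tree, {"A": 2.0, "B": 4.0, "C": 6.0})
    c = cs.contrasts
    assert contrast_variance(cs) == pytest.approx(np.var(c))
    two = read_newick("(A:1,B:1);")
    with pytest.raises(PhyloError, match="degenerate"):
        contrast_variance(independent_contrasts(two, {"A": 1.0, "B": 0.0}))


class TestSignalTest:
    def test_seeded_p_value_reproducible(self):
        tree = simulate_tree(8, seed=3)
        traits = simulate_bm_traits(tree, 1.0, 0.0, seed=4)
        a = signal_test(tree, traits, n_randomizations=199, seed=9)
        b = signal_test(tree, traits, n_randomizations=199, seed=9)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_variances, b.null_variances)

    def test_affine_invariance_of_p(self):
        """Rescaling and shifting the trait rescales observed and null
        variances identically, so the p-value is unchanged."""
        tree = simulate_tree(16, seed=5)
        traits = simulate_bm_traits(tree, 1.0, 0.0, seed=6)
        shifted = {k: -3.7 * v + 11.0 for k, v in traits.items()}
        p1 = signal_test(tree, traits, n_randomizations=199, seed=1).p_value
        p2 = signal_test(tree, shifted, n_randomizations=199, seed=1).p_value
        assert p1 == p2

    def test_constant_trait_degenerate(self):
        tree = simulate_tree(8, seed=3)
        with pytest.raises(PhyloError, match="constant"):
            signal_test(tree, {t: 1.0 for t in tree.tip_labels}, 199, 0)

    def test_p_value_always_positive(self):
        tree = simulate_tree(24, seed=8)
        traits = simulate_bm_traits(tree, 1.0, 0.0, seed=9)
        res = signal_test(tree, traits, n_randomizations=199, seed=2)
        assert 0 < res.p_value <= 1
        assert len(res.null_variances) == 199


class TestPicCorrelation:
    def test_proportional_contrasts_give_unit_correlation(self):
        tree = simulate_tree(10, seed=1)
        traits = simulate_bm_traits(tree, 1.0, 0.0, seed=2)
        cx = independent_contrasts(tree, traits, "x")
        cy = independent_contrasts(
            tree, {k: 2 * v for k, v in traits.items()}, "y"
        )
        res = pic_correlation(cx, cy)
        assert res.r == pytest.approx(1.0)
        assert res.p_parametric == pytest.approx(0.0, abs=1e-12)
        neg = independent_contrasts(tree, {k: -v for k, v in traits.items()}, "z")
        assert pic_correlation(cx, neg).r == pytest.approx(-1.0)

    def test_mismatched_trees_rejected(self):
        t1, t2 = simulate_tree(8, seed=1), simulate_tree(9, seed=1)
        c1 = independent_contrasts(t1, simulate_bm_traits(t1, 1, 0, 2))
        c2 = independent_contrasts(t2, simulate_bm_traits(t2, 1, 0, 2))
        with pytest.raises(PhyloError):
            pic_correlation(c1, c2)

    def test_randomization_p_close_to_parametric_under_null(self):
        tree = simulate_tree(32, seed=4)
        cx = independent_contrasts(tree, simulate_bm_traits(tree, 1, 0, 5), "x")
        cy = independent_contrasts(tree, simulate_bm_traits(tree, 1, 0, 6), "y")
        res = pic_correlation(cx, cy, n_randomizations=999, seed=0)
        assert abs(res.p_parametric - res.p_randomization) < 0.12


@pytest.mark.parametrize(
    "label,code",
    [("dweller", 0.0), ("tunneler", 1.0), ("roller", 2.0), ("Tunneler", 1.0)],
)
def test_encode_nesting(label, code):
    assert encode_nesting(label) == code


def test_encode_nesting_unknown():
    with pytest.raises(PhyloError):
        encode_nesting("burrower")
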