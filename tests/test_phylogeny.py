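import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from coevotest import (
    Phylogeny,
    TraitTable,
    evolutionary_covariance,
    independent_contrasts,
    parse_newick,
)


class TestParseNewick:
    def test_two_tip(self):
        t = parse_newick("(A:1,B:1);")
        assert sorted(t.tip_labels) == ["A", "B"]
        assert t.height == 1.0

    def test_three_tip_structure(self, three_tip_tree):
        assert three_tip_tree.n_tips == 3
        assert len(three_tip_tree.tree.seed_node.child_nodes()) == 2

    def test_round_trip(self, yule16):
        again = parse_newick(yule16.to_newick())
        assert sorted(again.tip_labels) == sorted(yule16.tip_labels)
        u1, tips1 = yule16.contrast_operator()
        u2, tips2 = again.contrast_operator()
        assert tips1 == tips2
        assert np.allclose(u1, u2)

    @pytest.mark.parametrize(
        "bad",
        [
            "((A:1,B:1):1;",  # unbalanced parentheses
            "(A:1,A:1);",  # duplicate tips
            "(A:1,B);",  # missing branch length
        ],
    )
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_newick(bad)

    def test_basal_polytomy_rejected(self):
        with pytest.raises(ValueError, match="polytomy|unrooted"):
            parse_newick("(A:1,B:1,C:1);")


class TestIndependentContrasts:
    def test_two_tip_hand_value(self):
        tree = parse_newick("(A:2,B:2);")
        table = TraitTable(
            pd.DataFrame({"x": [2.0, 0.0], "y": [1.0, 1.0]}, index=["A", "B"])
        )
        cs = independent_contrasts(tree, table)
        assert cs.contrasts[:, 0] == pytest.approx([1.0])  # (2-0)/sqrt(4)
        assert cs.contrasts[:, 1] == pytest.approx([0.0])

    def test_three_tip_hand_values(self, three_tip_tree, three_tip_table):
        cs = independent_contrasts(three_tip_tree, three_tip_table)
        got = sorted(np.abs(cs.contrasts[:, 0]))
        # cherry contrast (1-(-1))/sqrt(2); ancestral value 0 on branch 1.5
        assert got == pytest.approx([0.0, np.sqrt(2.0)])

    def test_identical_tip_values_give_zero(self, yule16):
        table = TraitTable(
            pd.DataFrame(
                {"x": np.full(16, 3.0), "y": np.full(16, -1.0)},
                index=yule16.tip_labels,
            )
        )
        cs = independent_contrasts(yule16, table)
        assert np.allclose(cs.contrasts, 0.0)

    def test_contrast_count_with_multifurcation(self):
        tree = parse_newick("((A:1,B:1,C:1):1,D:2);")
        table = TraitTable(
            pd.DataFrame(
                {"x": [1.0, 2.0, 3.0, 4.0], "y": [0.0, 1.0, 0.0, 1.0]},
                index=list("ABCD"),
            )
        )
        cs = independent_contrasts(tree, table)
        assert cs.contrasts.shape == (3, 2)

    def test_cherry_order_flips_sign_only(self):
        a = parse_newick("((A:1,B:1):1,C:2);")
        b = parse_newick("((B:1,A:1):1,C:2);")
        table = TraitTable(
            pd.DataFrame({"x": [1.0, -1.0, 0.5], "y": [0.3, 0.9, -0.2]}, index=list("ABC"))
        )
        ca = independent_contrasts(a, table).contrasts
        cb = independent_contrasts(b, table).contrasts
        assert np.allclose(np.abs(ca), np.abs(cb))
        cov_a, _ = evolutionary_covariance(independent_contrasts(a, table))
        cov_b, _ = evolutionary_covariance(independent_contrasts(b, table))
        assert np.allclose(cov_a.entries, cov_b.entries)

    def test_zero_cherry_rejected_without_floor(self):
        tree = parse_newick("((A:0,B:0):1,C:2);")
        table = TraitTable(
            pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 0.0, 2.0]}, index=list("ABC"))
        )
        with pytest.raises(ValueError, match="cherry"):
            independent_contrasts(tree, table, zero_branch_floor=0)
        # with the default floor the contrasts are computable
        cs = independent_contrasts(tree, table)
        assert np.isfinite(cs.contrasts).all()

    def test_missing_tip_rejected(self, three_tip_tree):
        table = TraitTable(
            pd.DataFrame({"x": [1.0, 2.0], "y": [0.0, 1.0]}, index=["A", "B"])
        )
        with pytest.raises(ValueError, match="missing"):
            independent_contrasts(three_tip_tree, table)

    def test_matches_ape_pic_oracle(self, yule16):
        """Cross-check the contrasts against an independent R implementation."""
        rng = np.random.default_rng(9)
        table = TraitTable(
            pd.DataFrame(
                {"x": rng.normal(size=16), "y": rng.normal(size=16)},
                index=yule16.tip_labels,
            )
        )
        cs = independent_contrasts(yule16, table)
        tips = yule16.tip_labels
        values = ",".join(str(v) for v in table.data.loc[tips, "x"])
        script = textwrap.dedent(
            f"""
            suppressMessages(library(ape))
            tree <- read.tree(text='{yule16.to_newick()}')
            x <- c({values})
            names(x) <- c({",".join(repr(t) for t in tips)})
            cat(sort(abs(pic(x, tree))), sep='\\n')
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        expected = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(np.sort(np.abs(cs.contrasts[:, 0])), expected, atol=1e-8)


class TestEvolutionaryCovariance:
    def test_proportional_traits_fully_correlated(self, yule16):
        rng = np.random.default_rng(1)
        x = rng.normal(size=16)
        table = TraitTable(
            pd.DataFrame({"x": x, "y": 2 * x}, index=yule16.tip_labels)
        )
        _, corr = evolutionary_covariance(independent_contrasts(yule16, table))
        assert corr.entries[0, 1] == pytest.approx(1.0)

    def test_single_contrast_rank_one(self):
        tree = parse_newick("(A:1,B:1);")
        table = TraitTable(
            pd.DataFrame({"x": [1.0, 0.0], "y": [0.0, 2.0]}, index=["A", "B"])
        )
        _, corr = evolutionary_covariance(independent_contrasts(tree, table))
        assert abs(corr.entries[0, 1]) == pytest.approx(1.0)

    def test_star_tree_equals_through_origin_pearson(self):
        # 6-tip star with equal branch lengths, binarized with zero-length
        # internal splits: contrasts span the centered tip space, so the
        # evolutionary correlation equals the through-origin Pearson
        # correlation of the centered tip values.
        newick = "(((((A:1,B:1):0,C:1):0,D:1):0,E:1):0,F:1);"
        tree = parse_newick(newick)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 3))
        table = TraitTable(
            pd.DataFrame(x, index=list("ABCDEF"), columns=["p", "q", "r"])
        )
        _, corr = evolutionary_covariance(
            independent_contrasts(tree, table, zero_branch_floor=0)
        )
        xc = x - x.mean(axis=0)
        s = xc.T @ xc
        expect = s / np.sqrt(np.outer(np.diag(s), np.diag(s)))
        assert np.allclose(corr.entries, expect, atol=1e-10)

    def test_rank_bounded_by_contrast_count(self, yule16):
        rng = np.random.default_rng(2)
        table = TraitTable(
            pd.DataFrame(
                rng.normal(size=(16, 20)),
                index=yule16.tip_labels,
                columns=[f"t{i}" for i in range(20)],
            )
        )
        cov, _ = evolutionary_covariance(independent_contrasts(yule16, table))
        rank = np.linalg.matrix_rank(cov.entries, tol=1e-10)
        assert rank <= 15

    def test_all_zero_contrast_trait_warns_nan(self, yule16):
        rng = np.random.default_rng(3)
        table = TraitTable(
            pd.DataFrame(
                {"x": np.full(16, 5.0), "y": rng.normal(size=16)},
                index=yule16.tip_labels,
            )
        )
        with pytest.warns(RuntimeWarning, match="all-zero"):
            _, corr = evolutionary_covariance(independent_contrasts(yule16, table))
        assert np.isnan(corr.entries[0, 1])
        assert corr.entries[0, 0] == 1.0

    def test_centered_option_matches_numpy(self, yule16):
        rng = np.random.default_rng(8)
        table = TraitTable(
            pd.DataFrame(
                rng.normal(size=(16, 3)),
                index=yule16.tip_labels,
                columns=list("abc"),
            )
        )
        cs = independent_contrasts(yule16, table)
        cov, _ = evolutionary_covariance(cs, center=True)
        assert np.allclose(cov.entries, np.cov(cs.contrasts, rowvar=False, ddof=1))
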