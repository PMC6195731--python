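"""Gene summaries, IQR hit calling, association tests, grouped means."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tilescope import call_hits, grouped_means, summarize_gene
from tilescope.screen_stats import test_associations as run_association_tests


class TestGeneSummary:
    def test_identical_distributions_zero_emd(self, rng):
        x = rng.normal(size=50)
        s = summarize_gene("g", x, x)
        assert s.emd_vs_controls == pytest.approx(0.0)

    def test_translation_property_of_emd(self, rng):
        x = rng.normal(size=80)
        s = summarize_gene("g", x + 2.0, x)
        assert s.emd_vs_controls == pytest.approx(2.0, abs=1e-9)

    def test_small_transport_plan(self):
        s = summarize_gene("g", [0.0, 1.0], [0.0])
        assert s.emd_vs_controls == pytest.approx(0.5)

    def test_quartiles_and_density(self):
        s = summarize_gene("g", [1, 2, 3, 4, 5], protein_length=10,
                           aa1_positions=[1, 4, 6, 8, 9])
        assert (s.q1, s.median, s.q3) == (2, 3, 4)
        assert s.iqr == 2
        assert s.guide_density == pytest.approx(0.5)
        assert s.mean_guide_distance == pytest.approx(2.0)

    def test_no_controls_null_emd(self):
        assert summarize_gene("g", [1, 2]).emd_vs_controls is None


class TestHitCalling:
    def _summary(self, scores):
        return summarize_gene("g", scores)

    def test_all_negative_gene_is_negative_hit(self):
        s = call_hits([self._summary([-1.0] * 10)])[0]
        assert s.hit and s.direction == "negative"

    def test_symmetric_gene_not_called(self):
        s = call_hits([self._summary([-1, -1, 1, 1])])[0]
        assert not s.hit and s.direction == "none"

    def test_three_quarters_boundary(self):
        # exactly 75% below zero: q3 lands below 0 by linear interpolation
        s = call_hits([self._summary([-3, -2, -1, 1])])[0]
        assert s.q3 == pytest.approx(-0.5)
        assert s.hit and s.direction == "negative"

    def test_user_hits_override(self):
        summaries = [self._summary([-1, -1, 1, 1])]
        s = call_hits(summaries, user_hits=["g"])[0]
        assert s.hit and s.direction in ("positive", "negative")
        s = call_hits(summaries, user_hits=["other"])[0]
        assert not s.hit

    def test_invariant_to_positive_rescaling(self, rng):
        for _ in range(10):
            x = rng.normal(-0.5, 1.0, 40)
            a = call_hits([self._summary(x)])[0]
            b = call_hits([self._summary(x * 3.7)])[0]
            assert a.hit == b.hit and a.direction == b.direction

    def test_planted_hit_recovered_exactly(self, scored_guides, screen):
        """End to end: the generated strong negative gene, and only it, is
        called a hit with the planted direction."""
        targeting = scored_guides.dropna(subset=["gene_id"])
        summaries = []
        for gene, grp in targeting.groupby("gene_id"):
            summaries.append(summarize_gene(str(gene), grp["score"]))
        call_hits(summaries)
        called = {s.gene_id: (s.hit, s.direction) for s in summaries}
        truth = screen.truth_genes.set_index("gene_id")
        for gene, (hit, direction) in called.items():
            assert hit == bool(truth.loc[gene, "true_hit"])
            if hit:
                assert direction == truth.loc[gene, "direction"]


class TestAssociations:
    def _frame(self, scores, **annotations):
        df = pd.DataFrame({"gene_id": "g", "score": scores})
        for k, v in annotations.items():
            df[k] = v
        return df

    def test_flat_binary_annotation_p_near_one(self):
        df = self._frame([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                         in_domain=[True] * 3 + [False] * 3)
        out = run_association_tests(df, scope="gene", annotations=["in_domain"])
        assert out.loc[0, "p_value"] == pytest.approx(1.0, abs=0.05)

    def test_perfect_monotone_annotation_rho_one(self):
        df = self._frame([1.0, 2.0, 3.0, 4.0], provean1=[1.0, 2.0, 3.0, 4.0])
        out = run_association_tests(df, scope="gene", annotations=["provean1"])
        assert out.loc[0, "statistic"] == pytest.approx(1.0)

    def test_recovers_simulated_rank_correlation(self):
        """score = -provean + noise at n=1000: Spearman rho within 0.1 of
        an independent simulation estimate of the same model."""
        rng = np.random.default_rng(42)
        n, sigma = 1000, 1.0
        provean = rng.normal(-4, 2, n)
        df = self._frame(-provean + rng.normal(0, sigma, n), provean1=provean)
        out = run_association_tests(df, scope="gene", annotations=["provean1"])
        # oracle: re-simulate the generator many times, average rank corr
        sims = []
        for s in range(30):
            r2 = np.random.default_rng(1000 + s)
            p = r2.normal(-4, 2, n)
            sims.append(sps.spearmanr(p, -p + r2.normal(0, sigma, n)).statistic)
        assert out.loc[0, "statistic"] == pytest.approx(np.mean(sims), abs=0.1)

    def test_degenerate_annotation_skipped_with_reason(self):
        df = self._frame([1.0, 2.0, 3.0], in_domain=[True, True, True])
        out = run_association_tests(df, scope="gene", annotations=["in_domain"])
        assert np.isnan(out.loc[0, "p_value"])
        assert "single level" in out.loc[0, "reason"]

    def test_pooled_uses_per_gene_zscores(self, rng):
        # one gene with huge variance must not dominate the pooled test
        g1 = pd.DataFrame({"gene_id": "g1", "score": rng.normal(0, 100, 50),
                           "provean1": rng.normal(size=50)})
        x = rng.normal(size=50)
        g2 = pd.DataFrame({"gene_id": "g2", "score": x, "provean1": x})
        out = run_association_tests(pd.concat([g1, g2], ignore_index=True),
                                scope="pooled", annotations=["provean1"])
        assert out.loc[0, "n"] == 100
        assert out.loc[0, "statistic"] > 0.3  # g2's perfect signal survives

    def test_planted_associations_have_expected_sign(self, annotated_guides):
        """In the generated screen, scores drop with conservation, order and
        domain membership; pooled tests on the hit gene recover that."""
        out = run_association_tests(
            annotated_guides, hit_genes=["GENE_A"], scope="pooled",
            annotations=["provean1", "disorder1", "in_domain"], bh=True,
        )
        out = out.set_index("annotation")
        # negative scores at negative provean => positive rank correlation
        assert out.loc["provean1", "statistic"] > 0.3
        assert out.loc["disorder1", "statistic"] > 0.3
        assert out.loc["in_domain", "p_value"] < 0.01
        assert (out["p_bh"].dropna() >= out["p_value"].dropna() - 1e-12).all()

    def test_multiclass_uses_kruskal(self, annotated_guides):
        out = run_association_tests(annotated_guides, scope="pooled",
                                annotations=["ss1", "aa1_letter"])
        assert (out["test"] == "kruskal").all()


class TestGroupedMeans:
    def test_single_cell_gets_all_guides(self):
        df = pd.DataFrame({
            "score": [-1.0, -2.0], "provean1": [-8.0, -9.0],
            "in_domain": [True, True],
        })
        out = grouped_means(df)
        cell = out[(out["conserved"]) & (out["in_domain"])].iloc[0]
        assert cell["pct"] == pytest.approx(100.0)
        assert out["pct"].sum() == pytest.approx(100.0)

    def test_planted_cell_means_recovered(self, rng):
        n = 400
        conserved = rng.random(n) < 0.5
        in_dom = rng.random(n) < 0.5
        means = {(True, True): -2.0, (True, False): -1.0,
                 (False, True): -0.5, (False, False): 0.0}
        score = np.array([means[(c, d)] for c, d in zip(conserved, in_dom)])
        df = pd.DataFrame({
            "score": score + rng.normal(0, 0.2, n),
            "provean1": np.where(conserved, -8.0, -2.0),
            "in_domain": in_dom,
        })
        out = grouped_means(df).set_index(["conserved", "in_domain"])
        for key, mu in means.items():
            se = 0.2 / np.sqrt(out.loc[key, "n"])
            assert out.loc[key, "mean_score"] == pytest.approx(mu, abs=4 * se)
        assert out["pct"].sum() == pytest.approx(100.0)

    def test_threshold_sign_inversion_swaps_membership(self):
        df = pd.DataFrame({
            "score": [0.0] * 4, "provean1": [-8, -7, -2, -1],
            "in_domain": [True] * 4,
        })
        lo = grouped_means(df, conservation_threshold=-6.0)
        hi = grouped_means(df, conservation_threshold=6.0)
        n_cons_lo = lo[lo["conserved"]]["n"].sum()
        n_cons_hi = hi[hi["conserved"]]["n"].sum()
        assert (n_cons_lo, n_cons_hi) == (2, 4)

    def test_disorder_as_second_factor(self, annotated_guides):
        out = grouped_means(annotated_guides, second_col="disorder1",
                            second_threshold=0.5)
        assert out["pct"].sum() == pytest.approx(100.0)
        assert out["n"].sum() == annotated_guides.dropna(
            subset=["score", "provean1", "disorder1"]).shape[0]
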