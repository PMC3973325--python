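import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gantcscope.genome import feature_sequence
from gantcscope.motifs import scan_motif
from gantcscope.enrichment import classify_de, fisher_enrichment, simple_de
from gantcscope.synthetic import (
    SyntheticPlan,
    generate_expression_dataset,
    generate_gene_sets,
    generate_genome,
    generate_ipd_dataset,
    generate_methylation_plan,
    generate_ortholog_panel,
)


class TestGenerateGenome:
    def test_deterministic_given_seed(self, small_plan):
        g1, f1, s1 = generate_genome(small_plan)
        g2, f2, s2 = generate_genome(small_plan)
        assert g1.sequence == g2.sequence
        assert f1.equals(f2) and s1.equals(s2)

    def test_zero_coding_density_means_no_coding_motifs(self):
        plan = SyntheticPlan(seed=5, genome_length=50_000, n_genes=50,
                             gene_length_mean=400, motif_density_coding=0.0,
                             n_under=0, n_asym=0)
        genome, features, sites = generate_genome(plan)
        assert (sites["compartment"] == "coding").sum() == 0
        for row in features.itertuples(index=False):
            assert scan_motif(feature_sequence(genome, row), "GANTC") == []

    def test_motif_complement_is_exactly_planted(self, small_bundle):
        _, genome, _, sites = small_bundle
        occ = scan_motif(genome.sequence, "GANTC", genome.circular)
        assert occ == sorted(sites["site"])

    def test_planted_sites_never_overlap(self, small_bundle):
        _, _, _, sites = small_bundle
        pos = np.sort(sites["site"].to_numpy())
        assert np.all(np.diff(pos) >= 5)

    def test_infeasible_density_rejected(self):
        plan = SyntheticPlan(seed=0, genome_length=20_000, n_genes=20,
                             gene_length_mean=300, motif_density_intergenic=500.0)
        with pytest.raises(ValueError, match="infeasible"):
            generate_genome(plan)

    def test_genes_non_overlapping_and_typed(self, small_bundle):
        _, _, features, _ = small_bundle
        assert np.all(features["start"].to_numpy()[1:] >= features["end"].to_numpy()[:-1])
        assert set(features["kind"]) <= {"protein_coding", "rna"}


class TestMethylationPlan:
    def test_gradient_endpoints(self):
        plan = SyntheticPlan(seed=0, genome_length=1000, gradient=(0.8, 0.1),
                             n_genes=2, gene_length_mean=100, n_under=0, n_asym=0)
        out = generate_methylation_plan(plan, [0, 500])
        origin, terminus = out.set_index("site").loc[0], out.set_index("site").loc[500]
        assert origin["full_fraction"] == pytest.approx(0.2)
        assert origin["f_plus"] == pytest.approx(0.6)  # 1 - h/2
        assert terminus["full_fraction"] == pytest.approx(0.9)
        assert terminus["f_plus"] == pytest.approx(0.95)

    def test_flat_gradient_fully_methylated(self):
        plan = SyntheticPlan(seed=0, genome_length=1000, gradient=(0.0, 0.0),
                             n_genes=2, gene_length_mean=100, n_under=0, n_asym=0)
        out = generate_methylation_plan(plan, [10, 250, 760])
        assert np.allclose(out[["f_plus", "f_minus"]], 1.0)

    def test_planted_under_and_asym_sites(self, small_plan, small_bundle):
        plan, _, _, sites = small_bundle
        out = generate_methylation_plan(plan, sites["site"].to_numpy())
        under = out[out["site_class"] == "under"]
        asym = out[out["site_class"] == "asym"]
        assert len(under) == plan.n_under and len(asym) == plan.n_asym
        assert (under[["f_plus", "f_minus"]] <= 0.01).all().all()
        for row in asym.itertuples(index=False):
            low = row.f_plus if row.asym_strand == "+" else row.f_minus
            high = row.f_minus if row.asym_strand == "+" else row.f_plus
            assert low <= 0.01 < high

    def test_too_many_planted_sites_rejected(self):
        plan = SyntheticPlan(seed=0, genome_length=1000, n_genes=2,
                             gene_length_mean=100, n_under=3, n_asym=3)
        with pytest.raises(ValueError, match="exceeds"):
            generate_methylation_plan(plan, [1, 2, 3])

    def test_strand_symmetry_of_gradient_sites(self, small_bundle):
        plan, _, _, sites = small_bundle
        out = generate_methylation_plan(plan, sites["site"].to_numpy())
        grad = out[out["site_class"] == "gradient"]
        assert np.allclose(grad["f_plus"], grad["f_minus"])


class TestIpdDataset:
    def _one_site_plan(self, **kw):
        return SyntheticPlan(seed=0, genome_length=1000, n_genes=2,
                             gene_length_mean=100, n_under=0, n_asym=0, **kw)

    def _meth(self, f):
        return pd.DataFrame(
            {"site": [100], "hemi_fraction": [0.0], "full_fraction": [1.0],
             "f_plus": [f], "f_minus": [f], "site_class": ["gradient"], "asym_strand": [""]}
        )

    def test_fully_methylated_noiseless_is_exact(self, small_bundle):
        _, genome, _, _ = small_bundle
        plan = self._one_site_plan(ipd_cv=0.0)
        obs = generate_ipd_dataset(genome, self._meth(1.0), plan)
        assert np.allclose(obs["ipd_ratio"], plan.r_full_true)

    def test_half_methylated_mixing_identity(self, small_bundle):
        _, genome, _, _ = small_bundle
        plan = self._one_site_plan(ipd_cv=0.0, coverage_mean=20_000)
        obs = generate_ipd_dataset(genome, self._meth(0.5), plan)
        # E[obs] = (r_full + 1) / 2 = 4.34; binomial SE ~ (r-1)/(2 sqrt(cov))
        assert np.allclose(obs["ipd_ratio"], 4.34, atol=3 * 6.68 / 2 / np.sqrt(20_000))

    def test_mixture_mean_f02_monte_carlo(self, small_bundle):
        """Brute-force check of E[obs] = f r + (1-f) at f = 0.2."""
        _, genome, _, _ = small_bundle
        rng = np.random.default_rng(0)
        draws = rng.binomial(50, 0.2, 10_000) / 50
        expected = draws * 7.68 + (1 - draws) * 1.0  # cv = 0 simulation
        plan = self._one_site_plan(ipd_cv=0.0, coverage_mean=50)
        meth = pd.concat([self._meth(0.2)] * 400, ignore_index=True)
        meth["site"] = np.arange(0, 2000, 5)
        obs = generate_ipd_dataset(genome, meth, plan)
        se = expected.std() / np.sqrt(len(obs))
        assert obs["ipd_ratio"].mean() == pytest.approx(2.336, abs=3 * se + 3 * expected.std() / np.sqrt(10_000))

    def test_reference_mode_forces_full_methylation(self, small_methylome):
        plan, genome, sites, meth, obs, ref = small_methylome
        # even planted-under sites read as methylated in the reference strain
        assert ref["ipd_ratio"].min() > 2.4

    def test_coverage_floor(self, small_bundle):
        _, genome, _, _ = small_bundle
        plan = self._one_site_plan(coverage_mean=0.01)
        obs = generate_ipd_dataset(genome, self._meth(1.0), plan)
        assert (obs["coverage"] >= 1).all()

    def test_deterministic(self, small_bundle):
        plan, genome, _, sites = small_bundle
        meth = generate_methylation_plan(plan, sites["site"].to_numpy())
        a = generate_ipd_dataset(genome, meth, plan)
        b = generate_ipd_dataset(genome, meth, plan)
        assert a.equals(b)


class TestExpressionDataset:
    def _flags(self, n, rng, p=0.3):
        idx = pd.Index([f"GENE_{i:04d}" for i in range(n)], name="gene_id")
        return pd.Series(rng.random(n) < p, index=idx)

    def _features(self, n):
        return pd.DataFrame({"feature_id": [f"GENE_{i:04d}" for i in range(n)]})

    def test_null_coupling_independence(self, rng):
        """With coupling 1 the planted-DE flag is independent of the motif
        flag: chi-squared rejection rate stays near its nominal level."""
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            plan = SyntheticPlan(seed=seed, motif_de_coupling=1.0, de_fraction=0.2)
            feats = self._features(400)
            flags = self._flags(400, np.random.default_rng(seed))
            _, truth = generate_expression_dataset(feats, flags, plan)
            table = pd.crosstab(truth["planted"] == "down", truth["has_motif"])
            if table.shape == (2, 2):
                _, p, _, _ = stats.chi2_contingency(table)
                rejections += p < 0.05
        assert rejections / n_seeds <= 0.12

    def test_type_i_rate_of_raw_pvalues_without_effects(self):
        """de_effect 0: raw Welch p-values are uniform (rate of p < 0.05
        matches 0.05) once each group has enough replicates for the
        Welch-Satterthwaite approximation; at triplicates the test is
        conservative but never anticonservative."""
        for n_reps, lo in ((6, 0.04), (3, 0.02)):
            hits = total = 0
            for seed in range(200):
                plan = SyntheticPlan(seed=seed, de_effect=0.0, de_fraction=0.1,
                                     n_replicates=n_reps)
                feats = self._features(100)
                flags = self._flags(100, np.random.default_rng(seed))
                matrix, _ = generate_expression_dataset(feats, flags, plan)
                out = simple_de(matrix, ["wt"] * n_reps + ["mut"] * n_reps)
                hits += (out["p_raw"] < 0.05).sum()
                total += len(out)
            assert lo <= hits / total <= 0.056

    def test_coupling_drives_downstream_enrichment(self):
        """Coupling 4 at 10% DE in 2000 genes: the fold-enrichment of the
        motif property among significant genes exceeds 1 almost always."""
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            plan = SyntheticPlan(seed=seed, motif_de_coupling=4.0, de_fraction=0.1,
                                 de_effect=2.0)
            feats = self._features(2000)
            flags = self._flags(2000, np.random.default_rng(10_000 + seed))
            matrix, truth = generate_expression_dataset(feats, flags, plan)
            out = simple_de(matrix, ["wt"] * 3 + ["mut"] * 3)
            c = classify_de(out)
            if not c.significant:
                continue
            r = fisher_enrichment(c.significant, set(flags.index[flags]), c.universe)
            wins += r.fold > 1
        assert wins / n_seeds >= 0.95

    def test_truth_table_counts(self, rng):
        plan = SyntheticPlan(seed=2, de_fraction=0.1, n_replicates=4)
        feats = self._features(500)
        matrix, truth = generate_expression_dataset(feats, self._flags(500, rng), plan)
        assert matrix.shape == (500, 8)
        assert (truth["planted"] != "none").sum() == 50
        assert set(truth.loc[truth["planted"] == "down", "effect"]) == {-plan.de_effect}

    def test_invalid_de_fraction_rejected(self, rng):
        plan = SyntheticPlan(seed=0, de_fraction=1.5)
        with pytest.raises(ValueError, match="de_fraction"):
            generate_expression_dataset(self._features(10), self._flags(10, rng), plan)


class TestGeneSetsAndOrthologs:
    def test_gene_sets_members_in_universe_with_overlap(self, rng):
        plan = SyntheticPlan(seed=4)
        feats = pd.DataFrame({"feature_id": [f"GENE_{i:04d}" for i in range(400)]})
        truth = pd.DataFrame(
            {"gene_id": feats["feature_id"],
             "planted": ["down"] * 40 + ["none"] * 360}
        )
        catalog, cog = generate_gene_sets(feats, truth, plan,
                                          set_specs={"reg": (100, 0.5)})
        assert catalog["reg"] <= set(feats["feature_id"])
        down = set(truth.loc[truth["planted"] == "down", "gene_id"])
        assert len(catalog["reg"] & down) == 40  # min(50, 40) planted overlap
        assert len(cog) == 400 and cog.str.len().eq(1).all()

    @pytest.mark.parametrize("p,expected", [(1.0, 5), (0.0, 0)])
    def test_ortholog_panel_degenerate_probs(self, p, expected):
        plan = SyntheticPlan(seed=0)
        feats = pd.DataFrame({"feature_id": [f"g{i}" for i in range(50)]})
        panel = generate_ortholog_panel(feats, plan, n_species=5, conservation_probs=p)
        assert (panel.sum(axis=1) == expected).all()

    def test_ortholog_panel_binomial_mean(self):
        plan = SyntheticPlan(seed=1)
        feats = pd.DataFrame({"feature_id": [f"g{i}" for i in range(1000)]})
        panel = generate_ortholog_panel(feats, plan, n_species=5, conservation_probs=0.6)
        assert panel.sum(axis=1).mean() == pytest.approx(3.0, abs=0.15)
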