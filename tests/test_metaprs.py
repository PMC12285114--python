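import numpy as np
import pandas as pd
import pytest

from cvdlife.metaprs import (
    CandidatePrs,
    GenotypeMatrix,
    aic_integrate,
    build_metaprs,
    clump_and_threshold,
    elasticnet_stack,
    harmonize,
    score_individuals,
    select_optimal_prs,
)
from cvdlife.synthetic import simulate_ld_panel


def gwas_frame(variants, beta, p):
    return pd.DataFrame(
        {
            "variant_id": variants["variant_id"],
            "chrom": variants["chrom"],
            "pos": variants["pos"],
            "effect_allele": variants["allele1"],
            "other_allele": variants["allele2"],
            "beta": beta,
            "p": p,
            "eaf": 0.3,
        }
    )


def brute_force_clump(gwas, panel, r2_threshold, window_bp):
    """Independent oracle: explicit greedy pass using np.corrcoef."""
    order = np.argsort(gwas["p"].to_numpy(), kind="stable")
    meta = panel.variants.set_index("variant_id")
    kept = []
    for i in order:
        vid = gwas["variant_id"].iloc[i]
        ok = True
        for kept_vid in kept:
            if meta.loc[vid, "chrom"] != meta.loc[kept_vid, "chrom"]:
                continue
            if abs(meta.loc[vid, "pos"] - meta.loc[kept_vid, "pos"]) > window_bp:
                continue
            ci = panel.variants.index[panel.variants["variant_id"] == vid][0]
            cj = panel.variants.index[panel.variants["variant_id"] == kept_vid][0]
            r = np.corrcoef(panel.dosages[:, ci], panel.dosages[:, cj])[0, 1]
            if r**2 >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(vid)
    return set(kept)


class TestClumpAndThreshold:
    def test_perfectly_correlated_pair_keeps_stronger(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.4, size=200).astype(float)
        dos = np.column_stack([col, col])
        variants = pd.DataFrame(
            {"variant_id": ["rs1", "rs2"], "chrom": "1", "pos": [1000, 2000],
             "allele1": ["A", "A"], "allele2": ["G", "G"]}
        )
        panel = GenotypeMatrix(dos, variants)
        gwas = gwas_frame(variants, beta=[0.3, 0.2], p=[1e-8, 1e-4])
        cands = clump_and_threshold(gwas, panel, r2_threshold=0.2, p_thresholds=[1.0])
        assert list(cands[0].weights["variant_id"]) == ["rs1"]

    def test_independent_variants_all_retained(self):
        dos, variants = simulate_ld_panel(400, 10, seed=1, block_size=1, within_r=0.0)
        panel = GenotypeMatrix(dos, variants)
        rng = np.random.default_rng(2)
        gwas = gwas_frame(variants, beta=rng.normal(size=10),
                          p=rng.uniform(0.01, 0.5, size=10))
        cands = clump_and_threshold(gwas, panel, r2_threshold=0.1, p_thresholds=[1.0])
        assert len(cands[0]) == 10

    def test_matches_brute_force_oracle_on_block_ld(self):
        """Greedy clumping on a 50-variant block-LD panel equals an
        independent brute-force greedy implementation."""
        dos, variants = simulate_ld_panel(600, 50, seed=4, block_size=5, within_r=0.6)
        panel = GenotypeMatrix(dos, variants)
        rng = np.random.default_rng(5)
        gwas = gwas_frame(variants, beta=rng.normal(size=50),
                          p=rng.uniform(1e-9, 1.0, size=50))
        for r2 in (0.1, 0.3):
            cands = clump_and_threshold(gwas, panel, r2_threshold=r2,
                                        p_thresholds=[1.0], window_kb=250)
            expected = brute_force_clump(gwas, panel, r2, 250_000)
            assert set(cands[0].weights["variant_id"]) == expected

    def test_p_threshold_subsets(self):
        dos, variants = simulate_ld_panel(300, 20, seed=6, block_size=1, within_r=0.0)
        panel = GenotypeMatrix(dos, variants)
        rng = np.random.default_rng(7)
        p = rng.uniform(1e-9, 1, size=20)
        gwas = gwas_frame(variants, beta=rng.normal(size=20), p=p)
        cands = clump_and_threshold(gwas, panel, 0.1, p_thresholds=[1e-4, 1e-2, 1.0])
        sizes = [len(c) for c in cands]
        assert sizes == sorted(sizes)
        assert len(cands[0]) == (p <= 1e-4).sum()

    def test_window_and_input_validation(self):
        dos, variants = simulate_ld_panel(50, 5, seed=0, block_size=1)
        panel = GenotypeMatrix(dos, variants)
        gwas = gwas_frame(variants, beta=np.ones(5), p=np.full(5, 0.5))
        with pytest.raises(ValueError):
            clump_and_threshold(gwas, panel, 0.1, window_kb=0)
        with pytest.raises(ValueError):
            clump_and_threshold(gwas.iloc[:0], panel, 0.1)


class TestScoring:
    @pytest.fixture()
    def panel20(self):
        dos, variants = simulate_ld_panel(100, 20, seed=9, block_size=1)
        return GenotypeMatrix(dos, variants)

    def test_matches_dot_product_oracle(self, panel20):
        rng = np.random.default_rng(10)
        w = rng.normal(size=20)
        prs = CandidatePrs(
            "t", "external",
            weights=pd.DataFrame(
                {"variant_id": panel20.variants["variant_id"],
                 "effect_allele": panel20.variants["allele1"], "weight": w}
            ),
        )
        raw = panel20.dosages @ w
        expected = (raw - raw.mean()) / raw.std()
        assert score_individuals(prs, panel20) == pytest.approx(expected)

    def test_zero_weights_rejected(self, panel20):
        prs = CandidatePrs(
            "t", "external",
            weights=pd.DataFrame(
                {"variant_id": panel20.variants["variant_id"],
                 "effect_allele": panel20.variants["allele1"],
                 "weight": np.zeros(20)}
            ),
        )
        with pytest.raises(ValueError, match="zero variance"):
            score_individuals(prs, panel20)

    def test_single_variant_is_standardized_dosage(self, panel20):
        prs = CandidatePrs(
            "t", "external",
            weights=pd.DataFrame(
                {"variant_id": ["rs1"], "effect_allele":
                 [panel20.variants["allele1"].iloc[0]], "weight": [1.0]}
            ),
        )
        d = panel20.dosages[:, 0]
        assert score_individuals(prs, panel20) == pytest.approx(
            (d - d.mean()) / d.std()
        )

    def test_allele_flip_sign_flip_invariance(self, panel20):
        """Swapping effect/other allele while negating the weight leaves
        the standardized score unchanged; variant order is irrelevant."""
        rng = np.random.default_rng(11)
        w = rng.normal(size=20)
        v = panel20.variants
        base = CandidatePrs(
            "t", "external",
            weights=pd.DataFrame(
                {"variant_id": v["variant_id"], "effect_allele": v["allele1"],
                 "other_allele": v["allele2"], "weight": w}
            ),
        )
        flipped_w = base.weights.copy()
        flipped_w.loc[::2, ["effect_allele", "other_allele"]] = (
            flipped_w.loc[::2, ["other_allele", "effect_allele"]].to_numpy()
        )
        flipped_w.loc[::2, "weight"] *= -1
        flipped = CandidatePrs("t", "external",
                               weights=flipped_w.sample(frac=1, random_state=1))
        a = score_individuals(base, panel20)
        b = score_individuals(flipped, panel20)
        assert a == pytest.approx(b)

    def test_ambiguous_variants_dropped(self):
        variants = pd.DataFrame(
            {"variant_id": ["rs1", "rs2"], "chrom": "1", "pos": [1, 2],
             "allele1": ["A", "A"], "allele2": ["T", "G"]}
        )
        table = pd.DataFrame(
            {"variant_id": ["rs1", "rs2"], "effect_allele": ["A", "A"],
             "other_allele": ["T", "G"], "weight": [1.0, 1.0]}
        )
        panel = GenotypeMatrix(np.ones((5, 2)), variants)
        aligned = harmonize(table, panel, effect_col="weight")
        assert list(aligned["variant_id"]) == ["rs2"]

    def test_no_overlap_rejected(self, panel20):
        prs = CandidatePrs(
            "t", "external",
            weights=pd.DataFrame(
                {"variant_id": ["nope"], "effect_allele": ["A"], "weight": [1.0]}
            ),
        )
        with pytest.raises(ValueError, match="overlap"):
            score_individuals(prs, panel20)


def _weights_from(panel, w):
    return pd.DataFrame(
        {"variant_id": panel.variants["variant_id"],
         "effect_allele": panel.variants["allele1"], "weight": w}
    )


@pytest.fixture(scope="module")
def liability_setup():
    rng = np.random.default_rng(20)
    dos, variants = simulate_ld_panel(2000, 60, seed=21, block_size=1)
    panel = GenotypeMatrix(dos, variants)
    true_w = rng.normal(size=60)
    score = dos @ true_w
    z = (score - score.mean()) / score.std()
    from scipy.special import expit
    y = (rng.uniform(size=2000) < expit(-1 + z)).astype(int)
    return panel, true_w, y


class TestSelection:

    def test_single_candidate_returned(self, liability_setup):
        panel, true_w, y = liability_setup
        prs = CandidatePrs("t", "external", weights=_weights_from(panel, true_w))
        assert select_optimal_prs([prs], panel, y) is prs

    def test_true_score_beats_noise(self, liability_setup):
        panel, true_w, y = liability_setup
        rng = np.random.default_rng(22)
        truth = CandidatePrs("truth", "external", weights=_weights_from(panel, true_w))
        noise = CandidatePrs("noise", "external",
                             weights=_weights_from(panel, rng.normal(size=60)))
        assert select_optimal_prs([noise, truth], panel, y).source == "truth"

    def test_tie_goes_to_first(self, liability_setup):
        panel, true_w, y = liability_setup
        a = CandidatePrs("a", "external", weights=_weights_from(panel, true_w))
        b = CandidatePrs("b", "external", weights=_weights_from(panel, true_w))
        assert select_optimal_prs([a, b], panel, y).source == "a"

    def test_outcome_must_have_two_classes(self, liability_setup):
        panel, true_w, _ = liability_setup
        prs = CandidatePrs("t", "external", weights=_weights_from(panel, true_w))
        with pytest.raises(ValueError):
            select_optimal_prs([prs], panel, np.zeros(panel.n, dtype=int))


class TestAicIntegrate:
    @staticmethod
    def _outcome(lin, seed, n):
        from scipy.special import expit
        rng = np.random.default_rng(seed)
        return (rng.uniform(size=n) < expit(-1 + lin)).astype(int)

    def test_identical_scores_choose_single(self):
        rng = np.random.default_rng(30)
        z = rng.normal(size=3000)
        y = self._outcome(0.5 * z, 31, 3000)
        choice, _ = aic_integrate(z, z.copy(), y)
        assert choice in ("eur_only", "eas_only")

    def test_independent_informative_scores_choose_both(self):
        rng = np.random.default_rng(32)
        z1, z2 = rng.normal(size=(2, 8000))
        y = self._outcome(0.4 * z1 + 0.4 * z2, 33, 8000)
        choice, combined = aic_integrate(z1, z2, y)
        assert choice == "both"
        assert abs(np.corrcoef(combined, z1)[0, 1]) > 0.2
        assert abs(np.corrcoef(combined, z2)[0, 1]) > 0.2

    def test_noise_score_excluded(self):
        rng = np.random.default_rng(34)
        z1, z2 = rng.normal(size=(2, 8000))
        y = self._outcome(0.5 * z1, 35, 8000)
        choice, combined = aic_integrate(z1, z2, y)
        assert choice == "eur_only"
        assert combined is not z2


class TestElasticNetStack:
    def test_informative_trait_recovered_among_noise(self):
        """One real trait among 13 noise traits: its coefficient is
        positive and the largest."""
        rng = np.random.default_rng(40)
        n, T = 5000, 14
        X = rng.normal(size=(n, T))
        from scipy.special import expit
        y = (rng.uniform(size=n) < expit(-1 + 0.5 * X[:, 0])).astype(int)
        model = elasticnet_stack(
            pd.DataFrame(X, columns=[f"t{i}" for i in range(T)]), y, seed=1
        )
        assert model.trait_weights.get("t0", 0.0) > 0
        others = [abs(v) for k, v in model.trait_weights.items() if k != "t0"]
        assert model.trait_weights["t0"] > (max(others) if others else 0)

    def test_grouping_property_on_duplicated_traits(self):
        rng = np.random.default_rng(41)
        n = 4000
        z = rng.normal(size=n)
        from scipy.special import expit
        y = (rng.uniform(size=n) < expit(-1 + 0.6 * z)).astype(int)
        X = pd.DataFrame(
            {"a": z + 0.01 * rng.normal(size=n), "b": z + 0.01 * rng.normal(size=n),
             "c": rng.normal(size=n)}
        )
        model = elasticnet_stack(X, y, seed=2, l1_ratios=(0.1,))
        wa, wb = model.trait_weights.get("a", 0), model.trait_weights.get("b", 0)
        assert wa > 0 and wb > 0
        assert abs(wa - wb) < 0.25 * max(wa, wb)

    def test_zero_signal_collapses_to_null_model(self):
        """Permuted labels: the all-zero solution wins in >= 9 of 10
        seeded replicates."""
        rng = np.random.default_rng(42)
        n, T = 1000, 8
        zero_runs = 0
        for rep in range(10):
            X = rng.normal(size=(n, T))
            y = rng.permutation(np.repeat([0, 1], n // 2))
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = elasticnet_stack(
                        pd.DataFrame(X, columns=[f"t{i}" for i in range(T)]),
                        y, seed=rep, folds=5,
                    )
            zero_runs += int(not model.trait_weights)
        assert zero_runs >= 9

    def test_requires_two_traits(self):
        with pytest.raises(ValueError):
            elasticnet_stack(pd.DataFrame({"a": [1.0, 2.0]}), np.array([0, 1]))


@pytest.fixture(scope="module")
def pipeline(small_panel):
    panel, summaries, W = small_panel
    from cvdlife.synthetic import simulate_liability_outcome

    y = simulate_liability_outcome(
        panel.dosages, W, [0.6, 0.3, 0.0], seed=50, prevalence=0.3
    )
    model, scores = build_metaprs(panel, summaries, y, seed=51, folds=5)
    return panel, model, scores, y


class TestFullPipeline:

    def test_variant_expansion_reproduces_stacked_score(self, pipeline):
        panel, model, scores, _ = pipeline
        stacked = np.zeros(panel.n)
        for t, coef in model.trait_weights.items():
            m, s = model.standardization[t]
            stacked += coef * (scores[t].to_numpy() - m) / s
        z = model.score(panel)
        assert abs(np.corrcoef(z, stacked)[0, 1]) > 1 - 1e-9

    def test_top_quintile_enriched_for_outcome(self, pipeline):
        """Directional sanity: simulated incidence is higher in the top
        meta-score quintile than the bottom."""
        panel, model, _, y = pipeline
        from cvdlife.exposures import categorize_prs

        cats = categorize_prs(model.score(panel))
        assert y[cats == "high"].mean() > y[cats == "low"].mean()

    def test_quintile_split_20_60_20(self, pipeline):
        panel, model, _, _ = pipeline
        from cvdlife.exposures import categorize_prs

        cats = categorize_prs(model.score(panel))
        n = panel.n
        assert (cats == "low").sum() == pytest.approx(0.2 * n, abs=1)
        assert (cats == "intermediate").sum() == pytest.approx(0.6 * n, abs=1)
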