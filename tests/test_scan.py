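"""Scanning, distance regression, sample summaries and downsampling."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from aiqtl import DataError, FAST_FIT, InsufficientDataError
from aiqtl.scan import (
    downsample_scan,
    fit_distance_logistic,
    predict_aiqtl_probability,
    run_aiqtl_scan,
    select_top_eqtl_per_gene,
    summarize_sample_alpha,
)
from conftest import make_scan_dataset, sbb_counts


def pair_row(gene, variant, log10p, dist, maf=0.2):
    return dict(
        variant_id=variant,
        gene_id=gene,
        tss_distance=dist,
        maf=maf,
        eqtl_log10_p=log10p,
        n_informative_samples=100,
        median_reads=30.0,
    )


class TestSelectTopEqtl:
    def test_strongest_association_wins(self):
        df = pd.DataFrame(
            [
                pair_row("g1", "v1", -8, 100),
                pair_row("g1", "v2", -20, 5000),
                pair_row("g1", "v3", -12, 50),
            ]
        )
        out = select_top_eqtl_per_gene(df)
        assert list(out["variant_id"]) == ["v2"]

    def test_tie_broken_by_distance_then_id(self):
        df = pd.DataFrame(
            [
                pair_row("g1", "vB", -10, 5000),
                pair_row("g1", "vA", -10, 100),
            ]
        )
        assert list(select_top_eqtl_per_gene(df)["variant_id"]) == ["vA"]
        df2 = pd.DataFrame(
            [pair_row("g1", "vB", -10, 100), pair_row("g1", "vA", -10, -100)]
        )
        assert list(select_top_eqtl_per_gene(df2)["variant_id"]) == ["vA"]

    def test_one_record_per_gene(self):
        df = pd.DataFrame(
            [pair_row("g1", "v1", -8, 10), pair_row("g2", "v2", -9, 10)]
        )
        assert len(select_top_eqtl_per_gene(df)) == 2

    def test_empty_input(self):
        assert select_top_eqtl_per_gene(pd.DataFrame()).empty


@pytest.fixture(scope="module")
def scan_dataset():
    return make_scan_dataset(n_genes=20, n_cis=5, n_samples=150, seed=7)


@pytest.fixture(scope="module")
def scan_result(scan_dataset):
    counts, genotypes, pairs, _ = scan_dataset
    return run_aiqtl_scan(counts, genotypes, pairs, FAST_FIT, detection_level=0.01)


class TestRunScan:
    def test_recovers_true_cis_genes(self, scan_dataset, scan_result):
        _, _, _, cis_genes = scan_dataset
        t = scan_result.table
        detected = set(t.loc[t["detected"] == True, "gene_id"])  # noqa: E712
        assert len(detected & cis_genes) >= 4  # >= 4 of 5 strong effects
        false_pos = detected - cis_genes
        assert len(false_pos) <= 2  # 15 nulls at level 0.01

    def test_every_pair_conserved_exactly_once(self, scan_dataset, scan_result):
        _, _, pairs, _ = scan_dataset
        t = scan_result.table
        assert len(t) == len(pairs)
        assert set(zip(t.gene_id, t.variant_id)) == set(
            zip(pairs.gene_id, pairs.variant_id)
        )
        assert (t["status"].notna()).all()

    def test_row_order_invariance(self, scan_dataset, scan_result):
        counts, genotypes, pairs, _ = scan_dataset
        shuffled = counts.sample(frac=1.0, random_state=1)
        res2 = run_aiqtl_scan(shuffled, genotypes, pairs, FAST_FIT, detection_level=0.01)
        pd.testing.assert_series_equal(
            res2.table["p_value"], scan_result.table["p_value"]
        )

    def test_relabel_invariance(self, scan_dataset, scan_result):
        counts, genotypes, pairs, _ = scan_dataset
        flipped = counts.copy()
        rng = np.random.default_rng(0)
        mask = rng.random(len(flipped)) < 0.5
        flipped.loc[mask, "a_count"] = (
            flipped.loc[mask, "total_count"] - flipped.loc[mask, "a_count"]
        )
        res2 = run_aiqtl_scan(flipped, genotypes, pairs, FAST_FIT, detection_level=0.01)
        assert (res2.table["p_value"] == scan_result.table["p_value"]).all()

    def test_small_het_group_gets_reason_code(self):
        counts, genotypes, pairs, _ = make_scan_dataset(
            n_genes=1, n_cis=0, n_samples=40, maf=0.05, seed=3
        )
        res = run_aiqtl_scan(counts, genotypes, pairs, FAST_FIT)
        assert res.table.loc[0, "status"] == "insufficient_het"
        assert pd.isna(res.table.loc[0, "p_value"])

    def test_unknown_pair_reported(self, scan_dataset):
        counts, genotypes, _, _ = scan_dataset
        pairs = pd.DataFrame([pair_row("nope", "v000", -10, 10)])
        res = run_aiqtl_scan(counts, genotypes, pairs, FAST_FIT)
        assert res.table.loc[0, "status"] == "no_counts"

    def test_empty_pairs_give_empty_result(self, scan_dataset):
        counts, genotypes, _, _ = scan_dataset
        res = run_aiqtl_scan(counts, genotypes, pd.DataFrame(columns=["gene_id", "variant_id"]), FAST_FIT)
        assert len(res.table) == 0

    def test_holm_never_detects_more_than_unadjusted(self, scan_dataset):
        counts, genotypes, pairs, _ = scan_dataset
        plain = run_aiqtl_scan(counts, genotypes, pairs, FAST_FIT, adjustment="none")
        holm = run_aiqtl_scan(counts, genotypes, pairs, FAST_FIT, adjustment="holm")
        assert holm.n_detected <= plain.n_detected


def logistic_synthetic(n=400, beta_up=-0.006, beta_down=-0.003, seed=11):
    """Detection outcomes drawn from a known logistic model over distance."""
    rng = np.random.default_rng(seed)
    dist = rng.integers(-800_000, 800_000, size=n)
    n_inf = rng.integers(50, 600, size=n)
    med = rng.uniform(5, 60, size=n)
    maf = rng.uniform(0.05, 0.5, size=n)
    lp = rng.uniform(-30, -5, size=n)
    d_kb = np.abs(dist) / 1e3
    eta = (
        1.0
        + beta_up * np.where(dist < 0, d_kb, 0)
        + beta_down * np.where(dist >= 0, d_kb, 0)
        + 0.002 * n_inf
        + 0.01 * med
        + 1.0 * maf
        - 0.05 * lp
        - 3.0
    )
    detected = rng.random(n) < expit(eta)
    df = pd.DataFrame(
        dict(
            gene_id=[f"g{i}" for i in range(n)],
            variant_id=[f"v{i}" for i in range(n)],
            tss_distance=dist,
            n_informative_samples=n_inf,
            median_reads=med,
            maf=maf,
            eqtl_log10_p=lp,
            p_value=0.5,  # marks the row as tested
            detected=detected,
        )
    )
    return df, dict(beta_up=beta_up, beta_down=beta_down)


class TestDistanceLogistic:
    def test_recovers_generating_coefficients(self):
        df, truth = logistic_synthetic()
        model = fit_distance_logistic(df)
        s = model.summary
        for term, true_val in [
            ("dist_upstream_kb", truth["beta_up"]),
            ("dist_downstream_kb", truth["beta_down"]),
        ]:
            est = s.loc[term, "coef"]
            se = s.loc[term, "std_err"]
            assert abs(est - true_val) < 2 * se
            assert est < 0
            assert s.loc[term, "p_value"] < 0.05

    def test_constant_response_aborts(self):
        df, _ = logistic_synthetic()
        df["detected"] = True
        with pytest.raises(DataError, match="constant"):
            fit_distance_logistic(df)

    def test_permuted_response_is_null(self):
        df, _ = logistic_synthetic()
        rng = np.random.default_rng(12)
        n_sig = 0
        for _ in range(50):
            shuffled = df.copy()
            shuffled["detected"] = rng.permutation(df["detected"].to_numpy())
            try:
                m = fit_distance_logistic(shuffled)
            except DataError:
                continue
            if (
                m.summary.loc["dist_upstream_kb", "p_value"] < 0.05
                or m.summary.loc["dist_downstream_kb", "p_value"] < 0.05
            ):
                n_sig += 1
        assert n_sig <= 5  # ~2 * level * 50 expected significant by chance

    def test_too_few_rows_rejected(self):
        df, _ = logistic_synthetic(n=20)
        with pytest.raises(InsufficientDataError):
            fit_distance_logistic(df)


class TestPredict:
    def test_mean_fitted_probability_matches_detection_rate(self):
        # with an intercept, logistic ML equates the mean fitted
        # probability to the observed rate (score equation)
        df, _ = logistic_synthetic()
        model = fit_distance_logistic(df)
        fitted = model.result.predict()
        assert np.mean(fitted) == pytest.approx(df["detected"].mean(), abs=1e-6)

    def test_curve_is_monotone_when_slope_negative(self):
        df, _ = logistic_synthetic()
        model = fit_distance_logistic(df)
        cov = dict(
            n_informative_samples=500,
            median_reads=30.0,
            maf=0.05,
            eqtl_log10_p=-20.0,
        )
        curve = predict_aiqtl_probability(model, cov, distance_grid=np.arange(0, 1e6, 1e5))
        probs = curve["probability"].to_numpy()
        assert (np.diff(probs) < 0).all()
        assert ((probs > 0) & (probs < 1)).all()

    def test_prediction_near_generating_model(self):
        df, truth = logistic_synthetic(n=2000, seed=13)
        model = fit_distance_logistic(df)
        cov = dict(
            tss_distance=-500_000,
            n_informative_samples=500,
            median_reads=30.0,
            maf=0.05,
            eqtl_log10_p=-20.0,
        )
        eta_true = (
            1.0 + truth["beta_up"] * 500 + 0.002 * 500 + 0.01 * 30 + 1.0 * 0.05
            - 0.05 * -20.0 - 3.0
        )
        pred = predict_aiqtl_probability(model, cov)
        assert pred == pytest.approx(expit(eta_true), abs=0.1)

    def test_missing_covariate_rejected(self):
        df, _ = logistic_synthetic()
        model = fit_distance_logistic(df)
        with pytest.raises(DataError, match="missing"):
            predict_aiqtl_probability(model, {"tss_distance": 0})


class TestSampleAlphaSummary:
    def test_tissue_medians_separate(self):
        rng = np.random.default_rng(21)
        rows = []
        for tissue, alpha in [("blood", 10.0), ("testis", 40.0)]:
            for s in range(12):
                sid = f"{tissue}_{s}"
                a, n = sbb_counts(rng, 60, alpha=alpha)
                rows += [
                    dict(sample_id=sid, gene_id=f"g{i}", a_count=ai, total_count=ni)
                    for i, (ai, ni) in enumerate(zip(a, n))
                ]
        counts = pd.DataFrame(rows)
        meta = pd.DataFrame(
            dict(
                sample_id=counts["sample_id"].unique(),
                tissue=[s.split("_")[0] for s in counts["sample_id"].unique()],
            )
        )
        summary = summarize_sample_alpha(counts, meta)
        med = summary.table.groupby("tissue")["alpha"].median()
        assert med["blood"] < med["testis"]

    def test_independent_covariate_not_significant(self):
        rng = np.random.default_rng(22)
        rows, ages = [], {}
        for s in range(30):
            sid = f"s{s}"
            ages[sid] = float(rng.integers(20, 70))
            a, n = sbb_counts(rng, 40, alpha=20.0)
            rows += [
                dict(sample_id=sid, gene_id=f"g{i}", a_count=ai, total_count=ni)
                for i, (ai, ni) in enumerate(zip(a, n))
            ]
        counts = pd.DataFrame(rows)
        meta = pd.DataFrame(
            dict(sample_id=list(ages), tissue="t", age=list(ages.values()))
        )
        summary = summarize_sample_alpha(counts, meta)
        assert (summary.correlations["p_holm"] > 0.05).all()

    def test_single_sample_yields_row_without_correlations(self):
        rng = np.random.default_rng(23)
        a, n = sbb_counts(rng, 30, alpha=15.0)
        counts = pd.DataFrame(
            dict(sample_id="only", gene_id=[f"g{i}" for i in range(30)], a_count=a, total_count=n)
        )
        summary = summarize_sample_alpha(counts)
        assert len(summary.table) == 1
        assert summary.correlations.empty


@pytest.fixture(scope="module")
def small_dataset():
    return make_scan_dataset(n_genes=4, n_cis=2, n_samples=120, seed=31)


class TestDownsample:
    def test_full_size_reproduces_full_scan(self, small_dataset):
        counts, genotypes, pairs, _ = small_dataset
        n = counts["sample_id"].nunique()
        full = run_aiqtl_scan(counts, genotypes, pairs, FAST_FIT, detection_level=0.01)
        ds = downsample_scan(counts, genotypes, pairs, [n], seed=5, config=FAST_FIT)
        tested = full.table["p_value"].notna()
        assert ds["detected_fraction"].iloc[0] == pytest.approx(
            float(full.table.loc[tested, "detected"].mean())
        )

    def test_detected_fraction_grows_with_size(self, small_dataset):
        counts, genotypes, pairs, _ = small_dataset
        n = counts["sample_id"].nunique()
        ds = downsample_scan(
            counts, genotypes, pairs, [40, n], n_draws=2, seed=5, config=FAST_FIT
        )
        frac = ds.groupby("size")["detected_fraction"].mean()
        assert frac.loc[n] >= frac.loc[40] - 1e-9

    def test_fixed_seed_reproduces(self, small_dataset):
        counts, genotypes, pairs, _ = small_dataset
        d1 = downsample_scan(counts, genotypes, pairs, [50], seed=9, config=FAST_FIT)
        d2 = downsample_scan(counts, genotypes, pairs, [50], seed=9, config=FAST_FIT)
        pd.testing.assert_frame_equal(d1, d2)

    def test_oversized_request_rejected(self, small_dataset):
        counts, genotypes, pairs, _ = small_dataset
        with pytest.raises(DataError):
            downsample_scan(counts, genotypes, pairs, [10_000], config=FAST_FIT)
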