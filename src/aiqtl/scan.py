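"""Dataset-level orchestration: QTL scanning and downstream analyses.

Connects the per-pair likelihood-ratio test to whole-dataset workflows: a
scan over many (gene, variant) pairs with explicit reason codes for
untestable pairs, selection of the strongest eQTL per gene, the logistic
regression of detection probability on distance to the transcription
start site (TSS) and power-related covariates, per-sample dispersion
summaries with covariate correlations, and downsampling of the sample set.

Tabular inputs are pandas DataFrames:

counts
    columns ``sample_id, gene_id, a_count, total_count``
genotypes
    columns ``sample_id, variant_id, cls`` with cls in {"het", "hom"}
pairs
    columns matching :class:`EqtlRecord`
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .datatypes import DataError, InsufficientDataError
from .model import FitConfig, aiqtl_test, fit_sample_alpha

__all__ = [
    "EqtlRecord",
    "ScanResult",
    "DistanceModel",
    "select_top_eqtl_per_gene",
    "run_aiqtl_scan",
    "fit_distance_logistic",
    "predict_aiqtl_probability",
    "summarize_sample_alpha",
    "downsample_scan",
]

PAIR_COLUMNS = [
    "variant_id",
    "gene_id",
    "tss_distance",
    "maf",
    "eqtl_log10_p",
    "n_informative_samples",
    "median_reads",
]


@dataclass(frozen=True)
class EqtlRecord:
    """One eQTL-eGene association considered as a candidate aiQTL.

    ``tss_distance`` is signed (variant position minus TSS on the gene's
    + strand orientation; negative = upstream).  ``eqtl_log10_p`` is
    log10 of the eQTL association p-value (more negative = stronger).
    ``n_informative_samples`` counts samples with at least two
    allele-specifically mapped reads for the gene.
    """

    variant_id: str
    gene_id: str
    tss_distance: int
    maf: float
    eqtl_log10_p: float
    n_informative_samples: int = 0
    median_reads: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise DataError(f"maf must lie in (0, 0.5], got {self.maf}")
        if self.n_informative_samples < 0:
            raise DataError("n_informative_samples must be >= 0")


@dataclass
class ScanResult:
    """Per-pair test results joined to their eQTL records.

    ``table`` has one row per input pair — tested rows carry the LRT and
    fitted parameters, untestable rows a reason code in ``status`` — so
    records are conserved through the scan.
    """

    table: pd.DataFrame
    detection_level: float
    adjustment: str

    @property
    def n_detected(self) -> int:
        return int((self.table["detected"] == True).sum())  # noqa: E712 (nullable bool)


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([asdict(r) for r in records])


def select_top_eqtl_per_gene(records) -> pd.DataFrame:
    """Keep each gene's most strongly associated eQTL.

    Ties on the association strength are broken by smaller |tss_distance|,
    then lexicographic variant_id, making the selection deterministic.
    """
    df = _records_frame(records)
    if df.empty:
        return df
    df = df.assign(_absd=df["tss_distance"].abs())
    df = df.sort_values(
        ["gene_id", "eqtl_log10_p", "_absd", "variant_id"],
        ascending=[True, True, True, True],
        kind="mergesort",
    )
    out = df.groupby("gene_id", sort=True).head(1).drop(columns="_absd")
    return out.reset_index(drop=True)


def _genotype_split(counts_g, geno_v):
    cls = dict(zip(geno_v["sample_id"], geno_v["cls"]))
    rows = counts_g[["sample_id", "a_count", "total_count"]].to_numpy(dtype=object)
    hom_a, hom_n, het_a, het_n = [], [], [], []
    for s, a, n in rows:
        c = cls.get(s)
        if c == "hom":
            hom_a.append(a)
            hom_n.append(n)
        elif c == "het":
            het_a.append(a)
            het_n.append(n)
    return (
        (np.array(hom_a, dtype=np.int64), np.array(hom_n, dtype=np.int64)),
        (np.array(het_a, dtype=np.int64), np.array(het_n, dtype=np.int64)),
    )


def run_aiqtl_scan(
    counts: pd.DataFrame,
    genotypes: pd.DataFrame,
    pairs,
    config: FitConfig | None = None,
    detection_level: float = 0.01,
    adjustment: str = "none",
) -> ScanResult:
    """Run the mixture LRT on every (gene, variant) pair.

    Untestable pairs (missing counts or genotypes, undersized genotype
    groups) are reported with a reason code, never dropped.  ``detected``
    applies ``detection_level`` after the chosen multiple-testing
    adjustment (none, holm or bh).
    """
    if adjustment not in ("none", "holm", "bh"):
        raise DataError(f"unknown adjustment {adjustment!r}")
    config = config or FitConfig()
    pair_df = _records_frame(pairs)
    rows = []
    counts_by_gene = dict(tuple(counts.groupby("gene_id", sort=False)))
    geno_by_variant = dict(tuple(genotypes.groupby("variant_id", sort=False)))
    for rec in pair_df.itertuples(index=False):
        row = {"gene_id": rec.gene_id, "variant_id": rec.variant_id}
        counts_g = counts_by_gene.get(rec.gene_id)
        geno_v = geno_by_variant.get(rec.variant_id)
        if counts_g is None or counts_g.empty:
            row["status"] = "no_counts"
        elif geno_v is None or geno_v.empty:
            row["status"] = "no_genotypes"
        else:
            hom, het = _genotype_split(counts_g, geno_v)
            try:
                res = aiqtl_test(hom, het, config)
                row.update(
                    status="ok",
                    n_hom=res.n_hom,
                    n_het=res.n_het,
                    lrt_stat=res.lrt_stat,
                    p_value=res.p_value,
                    alpha1=res.alt_fit.alpha1,
                    alpha2=res.alt_fit.alpha2,
                    pi_null=res.null_fit.pi,
                    pi_hom=res.alt_fit.pi_hom,
                    pi_het=res.alt_fit.pi_het,
                )
            except InsufficientDataError as err:
                row["status"] = err.reason
        rows.append(row)
    table = pd.DataFrame(rows)
    if "p_value" not in table.columns:
        table["p_value"] = np.nan
    tested = table["p_value"].notna()
    table["p_adjusted"] = np.nan
    if tested.any():
        p = table.loc[tested, "p_value"].to_numpy()
        if adjustment == "none":
            p_adj = p
        else:
            method = {"holm": "holm", "bh": "fdr_bh"}[adjustment]
            p_adj = multipletests(p, method=method)[1]
        table.loc[tested, "p_adjusted"] = p_adj
    table["detected"] = pd.array(
        table["p_adjusted"].to_numpy() < detection_level, dtype="boolean"
    )
    table.loc[~tested, "detected"] = pd.NA
    # keep exactly one output row per input pair, in input order
    extra = pair_df.drop(columns=["gene_id", "variant_id"]).reset_index(drop=True)
    table = pd.concat([table.reset_index(drop=True), extra], axis=1)
    return ScanResult(table=table, detection_level=detection_level, adjustment=adjustment)


# ---------------------------------------------------------------------------
# Distance-to-TSS logistic regression

_COVARIATES = ["n_informative_samples", "median_reads", "maf", "eqtl_log10_p"]


@dataclass
class DistanceModel:
    """Fitted logistic regression of aiQTL detection on TSS distance.

    The linear predictor uses |distance| in kilobases with separate
    slopes for upstream (negative signed distance) and downstream
    variants, allowing the asymmetric decay seen in real data, plus the
    power covariates.
    """

    result: object
    feature_names: list[str]

    def design_row(self, covariates: dict) -> np.ndarray:
        missing = [
            k
            for k in ["tss_distance"] + _COVARIATES
            if k not in covariates
        ]
        if missing:
            raise DataError(f"missing covariates: {missing}")
        d = float(covariates["tss_distance"])
        row = [
            1.0,
            abs(d) / 1e3 if d < 0 else 0.0,
            abs(d) / 1e3 if d >= 0 else 0.0,
        ] + [float(covariates[k]) for k in _COVARIATES]
        return np.asarray(row)

    @property
    def summary(self) -> pd.DataFrame:
        res = self.result
        return pd.DataFrame(
            {
                "coef": res.params,
                "std_err": res.bse,
                "z": res.tvalues,
                "p_value": res.pvalues,
            },
            index=self.feature_names,
        )


def _distance_design(df: pd.DataFrame) -> pd.DataFrame:
    d = df["tss_distance"].astype(float)
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "dist_upstream_kb": np.where(d < 0, np.abs(d) / 1e3, 0.0),
            "dist_downstream_kb": np.where(d >= 0, np.abs(d) / 1e3, 0.0),
        },
        index=df.index,
    )
    for c in _COVARIATES:
        X[c] = df[c].astype(float)
    return X


def fit_distance_logistic(scan_table: pd.DataFrame, min_rows: int = 50) -> DistanceModel:
    """Fit detection probability as a logistic function of TSS distance.

    ``scan_table`` is a :class:`ScanResult` table (tested rows with a
    boolean ``detected`` joined to the eQTL covariates).  Degenerate
    inputs (constant response, perfect separation, rank deficiency) abort
    with a diagnostic rather than returning a silently unstable fit.
    """
    df = scan_table.loc[scan_table["p_value"].notna()].copy()
    if len(df) < min_rows:
        raise InsufficientDataError(
            "insufficient_rows", f"need >= {min_rows} tested pairs, got {len(df)}"
        )
    y = df["detected"].astype(float)
    if y.nunique() < 2:
        raise DataError(
            "constant response: every pair has the same detection outcome; "
            "logistic model is inestimable (complete separation)"
        )
    X = _distance_design(df)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise DataError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            "check for collinear covariates"
        )
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except PerfectSeparationError as err:  # pragma: no cover
        raise DataError(f"perfect separation: {err}") from err
    if not res.mle_retvals.get("converged", False):
        raise DataError("logistic fit did not converge")
    return DistanceModel(result=res, feature_names=list(X.columns))


def predict_aiqtl_probability(
    model: DistanceModel,
    covariates: dict,
    distance_grid: Sequence[float] | None = None,
):
    """Predicted detection probability at given covariates.

    With ``distance_grid``, returns a DataFrame of probabilities along a
    TSS-distance curve at otherwise fixed covariates (e.g. 500 informative
    samples, median 30 reads, eqtl_log10_p = -20).
    """
    if distance_grid is None:
        eta = float(model.design_row(covariates) @ model.result.params)
        return float(1.0 / (1.0 + np.exp(-eta)))
    rows = []
    for d in distance_grid:
        cov = dict(covariates)
        cov["tss_distance"] = d
        eta = float(model.design_row(cov) @ model.result.params)
        rows.append({"tss_distance": d, "probability": 1.0 / (1.0 + np.exp(-eta))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-sample dispersion summaries


@dataclass
class SampleAlphaSummary:
    """Per-sample alpha fits joined to metadata, plus covariate tests."""

    table: pd.DataFrame
    correlations: pd.DataFrame


def summarize_sample_alpha(
    counts: pd.DataFrame,
    sample_metadata: pd.DataFrame | None = None,
    config: FitConfig | None = None,
    group_col: str = "tissue",
) -> SampleAlphaSummary:
    """Fit one dispersion parameter per sample and test covariates.

    For each group (tissue), numeric covariates are tested by Spearman
    correlation with alpha and two-level covariates by a Wilcoxon
    rank-sum test; p-values are Holm-adjusted across groups within each
    covariate.  Samples whose fit fails the minimum-data filter are
    reported with a reason instead of a fit.
    """
    config = config or FitConfig()
    rows = []
    for sample_id, sub in counts.groupby("sample_id", sort=True):
        row = {"sample_id": sample_id}
        try:
            fit = fit_sample_alpha(
                (sub["a_count"].to_numpy(), sub["total_count"].to_numpy()),
                config,
                sample_id=str(sample_id),
            )
            row.update(
                alpha=fit.alpha,
                n_obs=fit.n_obs,
                loglik=fit.loglik,
                at_bound=fit.at_bound,
                status="ok",
            )
        except InsufficientDataError as err:
            row["status"] = err.reason
        rows.append(row)
    table = pd.DataFrame(rows)
    if sample_metadata is not None:
        missing = set(table["sample_id"]) - set(sample_metadata["sample_id"])
        table = table.merge(sample_metadata, on="sample_id", how="left")
        if missing:
            table["metadata_missing"] = table["sample_id"].isin(missing)
    corr = _alpha_covariate_tests(table, sample_metadata, group_col)
    return SampleAlphaSummary(table=table, correlations=corr)


def _alpha_covariate_tests(table, sample_metadata, group_col):
    cols = ["group", "covariate", "kind", "statistic", "p_value"]
    if sample_metadata is None or "alpha" not in table.columns:
        return pd.DataFrame(columns=cols + ["p_holm"])
    fitted = table[table["status"] == "ok"]
    if len(fitted) < 3:
        return pd.DataFrame(columns=cols + ["p_holm"])
    covars = [
        c
        for c in sample_metadata.columns
        if c not in ("sample_id", group_col)
    ]
    groups = (
        fitted.groupby(group_col)
        if group_col in fitted.columns
        else [("all", fitted)]
    )
    rows = []
    for gname, g in groups:
        for c in covars:
            vals = g[[c, "alpha"]].dropna()
            if len(vals) < 3:
                continue
            col = vals[c]
            if col.nunique() == 2:
                lv = sorted(col.unique())
                x = vals.loc[col == lv[0], "alpha"]
                y = vals.loc[col == lv[1], "alpha"]
                if len(x) < 2 or len(y) < 2:
                    continue
                res = stats.mannwhitneyu(x, y, alternative="two-sided")
                rows.append(
                    dict(
                        group=gname,
                        covariate=c,
                        kind="rank_sum",
                        statistic=float(res.statistic),
                        p_value=float(res.pvalue),
                    )
                )
            elif pd.api.types.is_numeric_dtype(col):
                rho, p = stats.spearmanr(col, vals["alpha"])
                rows.append(
                    dict(
                        group=gname,
                        covariate=c,
                        kind="spearman",
                        statistic=float(rho),
                        p_value=float(p),
                    )
                )
    corr = pd.DataFrame(rows, columns=cols)
    corr["p_holm"] = np.nan
    for c, sub in corr.groupby("covariate"):
        corr.loc[sub.index, "p_holm"] = multipletests(
            sub["p_value"].to_numpy(), method="holm"
        )[1]
    return corr


# ---------------------------------------------------------------------------
# Downsampling


def downsample_scan(
    counts: pd.DataFrame,
    genotypes: pd.DataFrame,
    pairs,
    sizes: Sequence[int],
    n_draws: int = 1,
    seed: int = 0,
    config: FitConfig | None = None,
    detection_level: float = 0.01,
) -> pd.DataFrame:
    """Re-run the scan on random sample subsets of decreasing size.

    For each size, ``n_draws`` subsets are drawn without replacement and
    the scan re-run; the output holds per-pair p-values per draw and the
    overall detected fraction with twice its standard error (an
    approximate 95% interval).  ``size == n_samples`` reproduces the full
    scan exactly (the "subsample" is the full sample set).
    """
    all_samples = np.array(sorted(counts["sample_id"].unique()))
    n_total = all_samples.size
    rows = []
    rng = np.random.default_rng(seed)
    for size in sizes:
        if size > n_total:
            raise DataError(f"size {size} exceeds available samples ({n_total})")
        for draw in range(n_draws):
            if size == n_total:
                chosen = all_samples
            else:
                chosen = rng.choice(all_samples, size=size, replace=False)
            mask = counts["sample_id"].isin(chosen)
            gmask = genotypes["sample_id"].isin(chosen)
            scan = run_aiqtl_scan(
                counts[mask],
                genotypes[gmask],
                pairs,
                config,
                detection_level=detection_level,
                adjustment="none",
            )
            tested = scan.table["p_value"].notna()
            n_pairs = int(tested.sum())
            frac = (
                float(scan.table.loc[tested, "detected"].mean())
                if n_pairs
                else float("nan")
            )
            se = (
                float(np.sqrt(frac * (1 - frac) / n_pairs)) if n_pairs else float("nan")
            )
            for r in scan.table.itertuples(index=False):
                rows.append(
                    {
                        "size": size,
                        "draw": draw,
                        "gene_id": r.gene_id,
                        "variant_id": r.variant_id,
                        "p_value": r.p_value,
                        "detected": r.detected,
                        "detected_fraction": frac,
                        "two_se": 2.0 * se,
                    }
                )
    return pd.DataFrame(rows)
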