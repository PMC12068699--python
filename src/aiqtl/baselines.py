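"""Comparator tests for genotype-associated allelic imbalance.

Three approaches used in earlier allele-specific-expression work, plus the
independent-fits likelihood ratio that the mixture model was designed to
replace:

``binomial_method``
    Classify each sample as imbalanced by an exact binomial test against
    0.5, then compare the proportion of imbalanced samples between
    heterozygotes and homozygotes.  Because a sample's power to reach
    significance grows with its read depth, this classification is biased
    by expression level — the depth confound the mixture model avoids.

``threshold_method``
    Classify samples by fixed cutoffs on the allelic proportion
    (outside (0.35, 0.65), strict inequalities), then compare proportions.

``wilcox_method``
    Compare the absolute departure of allelic proportions from 0.5
    between the genotype groups with a Wilcoxon rank-sum test.

``indep_bb_test``
    Fit group-specific vs shared symmetric beta-binomials and compare by
    LRT.  A single sample with extreme imbalance and very high coverage
    can dominate this statistic, which is the documented failure mode
    motivating the mixture formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import DataError, InsufficientDataError, as_count_arrays
from .model import FitConfig, _kernel
from scipy.optimize import minimize_scalar

__all__ = [
    "BaselineResult",
    "binomial_method",
    "threshold_method",
    "wilcox_method",
    "indep_bb_test",
]


@dataclass(frozen=True)
class BaselineResult:
    """Result of one comparator test on a (gene, variant) pair.

    ``contingency`` is the 2x2 table [[het_imbalanced, het_balanced],
    [hom_imbalanced, hom_balanced]]; present only for the classification
    methods (binomial, threshold).
    """

    method: str
    statistic: float
    p_value: float
    n_het: int
    n_hom: int
    contingency: tuple[tuple[int, int], tuple[int, int]] | None = None


def _require_nonempty(a_hom, a_het):
    if a_hom.size == 0:
        raise InsufficientDataError("insufficient_hom", "hom group is empty")
    if a_het.size == 0:
        raise InsufficientDataError("insufficient_het", "het group is empty")


def _proportion_test(het_flags, hom_flags, method, group_test="fisher"):
    table = np.array(
        [
            [int(het_flags.sum()), int((~het_flags).sum())],
            [int(hom_flags.sum()), int((~hom_flags).sum())],
        ]
    )
    if group_test == "fisher":
        stat, p = stats.fisher_exact(table, alternative="two-sided")
    elif group_test == "chi2":
        stat, p, _, _ = stats.chi2_contingency(table)
    else:
        raise DataError(f"unknown group test {group_test!r}")
    return BaselineResult(
        method=method,
        statistic=float(stat),
        p_value=float(p),
        n_het=int(het_flags.size),
        n_hom=int(hom_flags.size),
        contingency=((int(table[0, 0]), int(table[0, 1])), (int(table[1, 0]), int(table[1, 1]))),
    )


def binomial_method(
    obs_hom,
    obs_het,
    per_sample_level: float = 0.05,
    group_test: str = "fisher",
) -> BaselineResult:
    """Per-sample exact binomial classification + group proportion test.

    Samples whose depth is too low to ever reach ``per_sample_level`` are
    retained: excluding them would hide, not fix, the depth bias this
    method suffers from.
    """
    a_hom, n_hom = as_count_arrays(obs_hom)
    a_het, n_het = as_count_arrays(obs_het)
    _require_nonempty(a_hom, a_het)

    def flags(a, n):
        # Two-sided exact binomial p at p0 = 0.5: the distribution is
        # symmetric and unimodal, so the minimum-likelihood two-sided
        # p-value equals the two symmetric tails, 2 * P(X <= min(a, n-a)).
        p = np.minimum(1.0, 2.0 * stats.binom.cdf(np.minimum(a, n - a), n, 0.5))
        return p < per_sample_level

    return _proportion_test(
        flags(a_het, n_het), flags(a_hom, n_hom), "binomial", group_test
    )


def threshold_method(
    obs_hom,
    obs_het,
    lo: float = 0.35,
    hi: float = 0.65,
    group_test: str = "fisher",
) -> BaselineResult:
    """Fixed-cutoff classification + group proportion test.

    A sample is called imbalanced when its allelic proportion is strictly
    below ``lo`` or strictly above ``hi``.
    """
    if lo >= hi:
        raise DataError(f"need lo < hi, got lo={lo}, hi={hi}")
    a_hom, n_hom = as_count_arrays(obs_hom)
    a_het, n_het = as_count_arrays(obs_het)
    _require_nonempty(a_hom, a_het)
    p_hom = a_hom / n_hom
    p_het = a_het / n_het
    return _proportion_test(
        (p_het < lo) | (p_het > hi),
        (p_hom < lo) | (p_hom > hi),
        "threshold",
        group_test,
    )


def wilcox_method(obs_hom, obs_het) -> BaselineResult:
    """Wilcoxon rank-sum on |proportion - 0.5| between genotype groups.

    Exact p-values for small samples (combined n <= 20), tie-corrected
    normal approximation otherwise.  Invariant under relabelling the A
    allele of any sample (the statistic uses absolute departures).
    """
    a_hom, n_hom = as_count_arrays(obs_hom)
    a_het, n_het = as_count_arrays(obs_het)
    _require_nonempty(a_hom, a_het)
    # |a/N - 0.5| computed as |2a - N| / 2N: the integer numerator makes
    # the departure bit-identical under a -> N - a relabelling
    d_het = np.abs(2 * a_het - n_het) / (2 * n_het)
    d_hom = np.abs(2 * a_hom - n_hom) / (2 * n_hom)
    n_tot = d_het.size + d_hom.size
    has_ties = np.unique(np.concatenate([d_het, d_hom])).size < n_tot
    if n_tot <= 20:
        method = (
            stats.PermutationMethod(n_resamples=200_000, rng=0)
            if has_ties
            else "exact"
        )
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        d_het, d_hom, alternative="two-sided", method=method
    )
    return BaselineResult(
        method="wilcox",
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        n_het=int(d_het.size),
        n_hom=int(d_hom.size),
    )


def _single_alpha_ml(a, n, bounds):
    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def neg(la):
        return -float(np.sum(_kernel(a, n, np.exp(la))))

    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8})
    return float(np.exp(res.x)), -float(res.fun)


def indep_bb_test(
    obs_hom, obs_het, config: FitConfig | None = None
) -> BaselineResult:
    """LRT of group-specific vs shared symmetric beta-binomial fits.

    One dispersion parameter per genotype group against a single shared
    one (1 df).  Sensitive to single extreme-imbalance high-coverage
    samples, unlike the mixture-weight test.
    """
    config = config or FitConfig()
    a_hom, n_hom = as_count_arrays(obs_hom)
    a_het, n_het = as_count_arrays(obs_het)
    _require_nonempty(a_hom, a_het)
    if a_hom.size < config.min_group_n or a_het.size < config.min_group_n:
        raise InsufficientDataError(
            "insufficient_group",
            f"both groups need >= {config.min_group_n} observations",
        )
    af_hom = a_hom.astype(float)
    nf_hom = n_hom.astype(float)
    af_het = a_het.astype(float)
    nf_het = n_het.astype(float)
    _, ll_hom = _single_alpha_ml(af_hom, nf_hom, config.alpha_bounds)
    _, ll_het = _single_alpha_ml(af_het, nf_het, config.alpha_bounds)
    a_all = np.concatenate([af_hom, af_het])
    n_all = np.concatenate([nf_hom, nf_het])
    _, ll_shared = _single_alpha_ml(a_all, n_all, config.alpha_bounds)
    lrt = max(0.0, 2.0 * (ll_hom + ll_het - ll_shared))
    return BaselineResult(
        method="indep_bb",
        statistic=float(lrt),
        p_value=float(stats.chi2.sf(lrt, df=1)),
        n_het=int(a_het.size),
        n_hom=int(a_hom.size),
    )


def baseline_test_fn(name: str, **kwargs):
    """Adapter returning a named baseline's p-value for the harness."""
    methods = {
        "binomial": binomial_method,
        "threshold": threshold_method,
        "wilcox": wilcox_method,
        "indep_bb": indep_bb_test,
    }
    fn = methods[name]

    def test(obs_hom, obs_het) -> float:
        return fn(obs_hom, obs_het, **kwargs).p_value

    test.__name__ = name
    return test
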