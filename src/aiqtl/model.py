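"""Genotype-dependent symmetric beta-binomial mixture model.

A gene's allele-specific counts across samples are modelled as a
two-component mixture of symmetric beta-binomials,

    f(A_i | N_i) = pi * SBB(A_i; alpha1, N_i) + (1 - pi) * SBB(A_i; alpha2, N_i),

where the components differ only in their dispersion parameter: after
fitting, components are relabelled so alpha1 >= alpha2, making ``pi`` the
weight of the more *balanced* component.  A candidate regulatory variant is
tested by letting the mixing weight depend on the sample's genotype class
(pi_het vs pi_hom) and comparing the fit against the shared-weight null
with a likelihood ratio test (1 df for the het/hom parameterization).

All fitting is deterministic given the input: multi-start Nelder-Mead in
the unconstrained space (log alpha1, log alpha2, logit pi), with the
alternative model always started from the null optimum (which guarantees
the nesting inequality) and the null re-started from the alternative
optimum using a group-size-weighted average of the mixing weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import betaln, expit, gammaln, log_expit, logit
from scipy.stats import chi2

from .datatypes import (
    AseObservation,
    FitError,
    InsufficientDataError,
    as_count_arrays,
)
from .sbb import sbb_logpmf

__all__ = [
    "FitConfig",
    "FAST_FIT",
    "MixtureFit",
    "AiqtlTestResult",
    "SampleAlphaFit",
    "mixture_loglik",
    "grouped_loglik",
    "fit_null_mixture",
    "fit_alt_mixture",
    "aiqtl_test",
    "aiqtl_test_groups",
    "fit_sample_alpha",
]

# Diverse (alpha1, alpha2, pi) starting points, drawn from the grid
# {2, 20, 200}^2 x {0.2, 0.5, 0.8} and ordered so that truncating the list
# (FitConfig.n_starts) keeps a balanced-vs-imbalanced spread.
_DEFAULT_STARTS: tuple[tuple[float, float, float], ...] = (
    (200.0, 2.0, 0.5),
    (20.0, 2.0, 0.8),
    (200.0, 20.0, 0.2),
    (200.0, 2.0, 0.8),
    (20.0, 2.0, 0.2),
    (200.0, 20.0, 0.5),
)


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs for maximum-likelihood fitting.

    min_reads
        Per-observation minimum total allele-mapped reads (observations
        below it are excluded before fitting).
    min_obs
        Minimum observations for a pooled (null or single-alpha) fit.
    min_group_n
        Minimum observations per genotype group for the grouped fit.
    alpha_bounds
        Fitted alpha is confined to this range; beyond it the pmf is
        numerically indistinguishable from its limits.
    n_starts
        Number of diverse starting points (in addition to any
        cross-initializations) used per optimization.
    """

    min_reads: int = 2
    min_obs: int = 20
    min_group_n: int = 10
    alpha_bounds: tuple[float, float] = (1e-3, 1e6)
    n_starts: int = 6
    maxiter: int = 2000
    fatol: float = 1e-8
    xatol: float = 1e-6


#: Reduced-start profile used for large simulation experiments.
FAST_FIT = FitConfig(n_starts=3, fatol=1e-6, xatol=1e-4)


@dataclass(frozen=True)
class MixtureFit:
    """Fitted two-component symmetric beta-binomial mixture.

    Exactly one of ``pi`` (shared-weight model) or the per-group weights
    (``pi_by_group``) is set.  Components are label-ordered so that
    ``alpha1 >= alpha2``; mixing weights refer to the alpha1 (balanced)
    component.
    """

    alpha1: float
    alpha2: float
    loglik: float
    pi: float | None = None
    pi_by_group: tuple[float, ...] | None = None
    converged: bool = True
    n_starts_used: int = 1
    at_alpha_bound: bool = False

    @property
    def pi_hom(self) -> float:
        assert self.pi_by_group is not None and len(self.pi_by_group) == 2
        return self.pi_by_group[0]

    @property
    def pi_het(self) -> float:
        assert self.pi_by_group is not None and len(self.pi_by_group) == 2
        return self.pi_by_group[1]

    @property
    def n_params(self) -> int:
        return 3 if self.pi is not None else 2 + len(self.pi_by_group)


@dataclass(frozen=True)
class AiqtlTestResult:
    """Likelihood-ratio test of genotype-dependent mixing weight."""

    lrt_stat: float
    df: int
    p_value: float
    null_fit: MixtureFit
    alt_fit: MixtureFit
    n_hom: int
    n_het: int


@dataclass(frozen=True)
class SampleAlphaFit:
    """Single dispersion parameter fitted to one sample across genes.

    Higher alpha means more balanced allelic expression across the
    sample's genes; low alpha means pervasive imbalance.
    """

    sample_id: str
    alpha: float
    n_obs: int
    loglik: float
    at_bound: bool = False


# ---------------------------------------------------------------------------
# Likelihood evaluation


def _mixture_terms(a, n, alpha1, alpha2, pi):
    """Per-observation log mixture density, computed with log-sum-exp."""
    lp1 = sbb_logpmf(a, n, alpha1)
    lp2 = sbb_logpmf(a, n, alpha2)
    if pi >= 1.0:
        return lp1
    if pi <= 0.0:
        return lp2
    return np.logaddexp(np.log(pi) + lp1, np.log1p(-pi) + lp2)


def mixture_loglik(obs, alpha1: float, alpha2: float, pi: float) -> float:
    """Log-likelihood of observations under the shared-weight mixture."""
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must lie in [0, 1], got {pi}")
    a, n = as_count_arrays(obs)
    return float(np.sum(_mixture_terms(a, n, alpha1, alpha2, pi)))


def grouped_loglik(
    obs_hom,
    obs_het,
    alpha1: float,
    alpha2: float,
    pi_hom: float,
    pi_het: float,
) -> float:
    """Full log-likelihood with genotype-specific mixing weights."""
    a_hom, n_hom = as_count_arrays(obs_hom)
    a_het, n_het = as_count_arrays(obs_het)
    if a_hom.size == 0 or a_het.size == 0:
        raise InsufficientDataError(
            "empty_group", "both genotype groups must be non-empty"
        )
    return mixture_loglik((a_hom, n_hom), alpha1, alpha2, pi_hom) + mixture_loglik(
        (a_het, n_het), alpha1, alpha2, pi_het
    )


# ---------------------------------------------------------------------------
# Fitting internals
#
# The optimizer works on a "kernel" likelihood that omits the binomial
# coefficient log C(N, a): that term is constant in the parameters and is
# added back once at the end.  Because a, N - a and N are small integers,
# gammaln is evaluated once per candidate alpha on the integer range
# 0..max(N) and gathered by index, instead of on the full data vectors.


def _choose_term(a, n):
    # grouped symmetrically in a <-> n - a so the sum is bit-identical
    # under allele relabelling
    return gammaln(n + 1.0) - (gammaln(a + 1.0) + gammaln(n - a + 1.0))


def _kernel(a, n, alpha):
    return betaln(a + alpha, n - a + alpha) - betaln(alpha, alpha)


def _filter_counts(obs, min_reads: int):
    a, n = as_count_arrays(obs)
    keep = n >= min_reads
    return a[keep].astype(np.float64), n[keep].astype(np.float64)


def _alpha_from(theta, log_bounds):
    return float(np.exp(np.clip(theta, log_bounds[0], log_bounds[1])))


class _KernelTable:
    """Per-dataset lookup machinery for fast kernel evaluation.

    Observations are deduplicated: identical (group, a, N) triples are
    collapsed to one entry with a multiplicity weight, and since the
    symmetric beta-binomial kernel only involves gamma functions of
    a + alpha, (N - a) + alpha and N + 2 alpha, gammaln is evaluated on
    the integer range 0..max(N) once per candidate alpha and gathered.
    ``kernel(alpha)`` returns the per-entry log pmf without the binomial
    coefficient.
    """

    def __init__(self, groups):
        a = np.concatenate([g[0] for g in groups]).astype(np.int64)
        n = np.concatenate([g[1] for g in groups]).astype(np.int64)
        # the kernel is symmetric in a <-> N - a, so observations are
        # canonicalized to min(a, N - a); fits are then bit-identical
        # under relabelling the A allele of any subset of samples
        a = np.minimum(a, n - a)
        gidx = np.repeat(np.arange(len(groups)), [g[0].size for g in groups])
        self.n_obs = a.size
        self.n_groups = len(groups)
        self.max_c = int(n.max())
        base = self.max_c + 1
        key = (gidx * base + a) * base + n
        uniq, counts = np.unique(key, return_counts=True)
        self._n_idx = (uniq % base).astype(np.int64)
        rest = uniq // base
        self._a_idx = (rest % base).astype(np.int64)
        self.group_idx = (rest // base).astype(np.int64)
        self._na_idx = self._n_idx - self._a_idx
        self.weights = counts.astype(np.float64)
        self._range = np.arange(base, dtype=np.float64)

    def kernel(self, alpha: float) -> np.ndarray:
        g1 = gammaln(self._range + alpha)
        g2 = gammaln(self._range + 2.0 * alpha)
        const = 2.0 * gammaln(alpha) - gammaln(2.0 * alpha)
        return g1[self._a_idx] + g1[self._na_idx] - g2[self._n_idx] - const


import math

try:  # compiled inner loop; the numpy path below is the reference
    from numba import njit as _njit

    @_njit(cache=False)
    def _neg_ll_jit(
        x, a_idx, na_idx, n_idx, gidx, w, n_range, lo, hi
    ):  # pragma: no cover
        la1 = min(max(x[0], lo), hi)
        la2 = min(max(x[1], lo), hi)
        alpha1 = math.exp(la1)
        alpha2 = math.exp(la2)
        r = n_range
        g1a = np.empty(r, dtype=np.float64)
        g2a = np.empty(r, dtype=np.float64)
        g1b = np.empty(r, dtype=np.float64)
        g2b = np.empty(r, dtype=np.float64)
        for j in range(r):
            g1a[j] = math.lgamma(j + alpha1)
            g2a[j] = math.lgamma(j + 2.0 * alpha1)
            g1b[j] = math.lgamma(j + alpha2)
            g2b[j] = math.lgamma(j + 2.0 * alpha2)
        c1 = 2.0 * math.lgamma(alpha1) - math.lgamma(2.0 * alpha1)
        c2 = 2.0 * math.lgamma(alpha2) - math.lgamma(2.0 * alpha2)
        n_groups = x.size - 2
        lt1 = np.empty(n_groups, dtype=np.float64)  # log pi_g
        lt2 = np.empty(n_groups, dtype=np.float64)  # log (1 - pi_g)
        for g in range(n_groups):
            t = x[2 + g]
            if t > 0.0:
                lt1[g] = -math.log1p(math.exp(-t))
                lt2[g] = -t - math.log1p(math.exp(-t))
            else:
                lt1[g] = t - math.log1p(math.exp(t))
                lt2[g] = -math.log1p(math.exp(t))
        total = 0.0
        for i in range(a_idx.size):
            g = gidx[i]
            l1 = g1a[a_idx[i]] + g1a[na_idx[i]] - g2a[n_idx[i]] - c1 + lt1[g]
            l2 = g1b[a_idx[i]] + g1b[na_idx[i]] - g2b[n_idx[i]] - c2 + lt2[g]
            d = l1 - l2
            if d >= 0.0:
                total += w[i] * (l1 + math.log1p(math.exp(-d)))
            else:
                total += w[i] * (l2 + math.log1p(math.exp(d)))
        return -total

    @_njit(cache=False)
    def _nm_jit(
        x0, a_idx, na_idx, n_idx, gidx, w, n_range, lo, hi, maxiter, fatol, xatol
    ):  # pragma: no cover
        """Nelder-Mead minimization of the mixture objective, fully compiled.

        Same simplex scheme and termination rule as scipy's implementation
        (reflection/expansion/contraction/shrink with the standard
        coefficients; stop when vertex spread < xatol and function spread
        < fatol).  Returns (x_best, f_best, converged).
        """
        ndim = x0.size
        rho, chi, psi, sigma = 1.0, 2.0, 0.5, 0.5
        sim = np.empty((ndim + 1, ndim), dtype=np.float64)
        fsim = np.empty(ndim + 1, dtype=np.float64)
        sim[0] = x0
        for k in range(ndim):
            y = x0.copy()
            if y[k] != 0.0:
                y[k] *= 1.05
            else:
                y[k] = 0.00025
            sim[k + 1] = y
        for k in range(ndim + 1):
            fsim[k] = _neg_ll_jit(sim[k], a_idx, na_idx, n_idx, gidx, w, n_range, lo, hi)
        order = np.argsort(fsim)
        sim = sim[order]
        fsim = fsim[order]
        it = 1
        while it < maxiter:
            df = 0.0
            dx = 0.0
            for k in range(1, ndim + 1):
                if abs(fsim[k] - fsim[0]) > df:
                    df = abs(fsim[k] - fsim[0])
                for j in range(ndim):
                    if abs(sim[k, j] - sim[0, j]) > dx:
                        dx = abs(sim[k, j] - sim[0, j])
            if df <= fatol and dx <= xatol:
                break
            xbar = np.zeros(ndim, dtype=np.float64)
            for k in range(ndim):
                xbar += sim[k]
            xbar /= ndim
            xr = (1.0 + rho) * xbar - rho * sim[ndim]
            fr = _neg_ll_jit(xr, a_idx, na_idx, n_idx, gidx, w, n_range, lo, hi)
            shrink = False
            if fr < fsim[0]:
                xe = (1.0 + rho * chi) * xbar - rho * chi * sim[ndim]
                fe = _neg_ll_jit(xe, a_idx, na_idx, n_idx, gidx, w, n_range, lo, hi)
                if fe < fr:
                    sim[ndim] = xe
                    fsim[ndim] = fe
                else:
                    sim[ndim] = xr
                    fsim[ndim] = fr
            elif fr < fsim[ndim - 1]:
                sim[ndim] = xr
                fsim[ndim] = fr
            elif fr < fsim[ndim]:
                xc = (1.0 + psi * rho) * xbar - psi * rho * sim[ndim]
                fc = _neg_ll_jit(xc, a_idx, na_idx, n_idx, gidx, w, n_range, lo, hi)
                if fc <= fr:
                    sim[ndim] = xc
                    fsim[ndim] = fc
                else:
                    shrink = True
            else:
                xcc = (1.0 - psi) * xbar + psi * sim[ndim]
                fcc = _neg_ll_jit(xcc, a_idx, na_idx, n_idx, gidx, w, n_range, lo, hi)
                if fcc < fsim[ndim]:
                    sim[ndim] = xcc
                    fsim[ndim] = fcc
                else:
                    shrink = True
            if shrink:
                for k in range(1, ndim + 1):
                    sim[k] = sim[0] + sigma * (sim[k] - sim[0])
                    fsim[k] = _neg_ll_jit(
                        sim[k], a_idx, na_idx, n_idx, gidx, w, n_range, lo, hi
                    )
            order = np.argsort(fsim)
            sim = sim[order]
            fsim = fsim[order]
            it += 1
        return sim[0], fsim[0], it < maxiter

    _HAVE_JIT = True
except ImportError:  # pragma: no cover
    _HAVE_JIT = False


def _make_grouped_objective(table: _KernelTable, log_bounds):
    """Negative kernel log-likelihood over (log a1, log a2, logit pi_g...)."""
    gidx = table.group_idx

    if _HAVE_JIT:
        a_idx = table._a_idx
        na_idx = table._na_idx
        n_idx = table._n_idx
        n_range = table.max_c + 1
        lo, hi = log_bounds

        w = table.weights

        def neg_ll(x):
            return _neg_ll_jit(
                np.asarray(x, dtype=np.float64),
                a_idx,
                na_idx,
                n_idx,
                gidx,
                w,
                n_range,
                lo,
                hi,
            )

        return neg_ll

    def neg_ll(x):
        alpha1 = _alpha_from(x[0], log_bounds)
        alpha2 = _alpha_from(x[1], log_bounds)
        k1 = table.kernel(alpha1)
        k2 = table.kernel(alpha2)
        t = np.asarray(x[2:])[gidx]
        return -float(
            np.sum(
                table.weights
                * np.logaddexp(log_expit(t) + k1, log_expit(-t) + k2)
            )
        )

    return neg_ll


def _run_starts(table: _KernelTable, log_bounds, starts, config: FitConfig):
    """Best-of-starts Nelder-Mead; returns (x_best, f_best, converged)."""
    best_x, best_f, best_ok = None, np.inf, False
    if _HAVE_JIT:
        for x0 in starts:
            x, f, ok = _nm_jit(
                np.asarray(x0, dtype=np.float64),
                table._a_idx,
                table._na_idx,
                table._n_idx,
                table.group_idx,
                table.weights,
                table.max_c + 1,
                log_bounds[0],
                log_bounds[1],
                config.maxiter,
                config.fatol,
                config.xatol,
            )
            if np.isfinite(f) and f < best_f:
                best_x, best_f, best_ok = x, float(f), bool(ok)
    else:
        neg_ll = _make_grouped_objective(table, log_bounds)
        for x0 in starts:
            res = minimize(
                neg_ll,
                np.asarray(x0, dtype=np.float64),
                method="Nelder-Mead",
                options={
                    "maxiter": config.maxiter,
                    "fatol": config.fatol,
                    "xatol": config.xatol,
                },
            )
            if np.isfinite(res.fun) and res.fun < best_f:
                best_x, best_f, best_ok = res.x, float(res.fun), bool(res.success)
    if best_x is None:
        raise FitError("all optimization starts produced a non-finite likelihood")
    return best_x, best_f, best_ok


def _canonical(alpha1, alpha2, pis):
    """Label-order components so alpha1 >= alpha2 (pi weights component 1)."""
    if alpha1 >= alpha2:
        return alpha1, alpha2, tuple(pis)
    return alpha2, alpha1, tuple(1.0 - p for p in pis)


def _clip_pi(p):
    return float(np.clip(p, 1e-12, 1.0 - 1e-12))


def _grouped_fit(groups_an, starts, config: FitConfig, const: float) -> MixtureFit:
    lo, hi = config.alpha_bounds
    log_bounds = (np.log(lo), np.log(hi))
    best_x, best_f, ok = _run_starts(_KernelTable(groups_an), log_bounds, starts, config)
    alpha1 = _alpha_from(best_x[0], log_bounds)
    alpha2 = _alpha_from(best_x[1], log_bounds)
    pis = [float(expit(t)) for t in best_x[2:]]
    alpha1, alpha2, pis = _canonical(alpha1, alpha2, pis)
    at_bound = any(
        np.isclose(np.log(al), b, atol=1e-9)
        for al in (alpha1, alpha2)
        for b in log_bounds
    )
    loglik = const - best_f
    if not np.isfinite(loglik):
        raise FitError("fitted log-likelihood is not finite")
    common = dict(
        alpha1=alpha1,
        alpha2=alpha2,
        loglik=loglik,
        converged=ok,
        n_starts_used=len(starts),
        at_alpha_bound=at_bound,
    )
    if len(groups_an) == 1:
        return MixtureFit(pi=pis[0], **common)
    return MixtureFit(pi_by_group=tuple(pis), **common)


def _null_starts(config: FitConfig):
    starts = []
    for a1, a2, p in _DEFAULT_STARTS[: max(1, config.n_starts)]:
        starts.append((np.log(a1), np.log(a2), logit(p)))
    return starts


def fit_null_mixture(
    obs,
    config: FitConfig | None = None,
    extra_starts: Sequence[Sequence[float]] = (),
    include_default_starts: bool = True,
) -> MixtureFit:
    """Fit the shared-weight (null) mixture by multi-start Nelder-Mead.

    ``extra_starts`` are additional unconstrained-space starting points
    (log alpha1, log alpha2, logit pi); used internally to initialize the
    null model from the alternative-model optimum (in which case the
    default grid, already explored, can be skipped).
    """
    config = config or FitConfig()
    a, n = _filter_counts(obs, config.min_reads)
    if a.size < config.min_obs:
        raise InsufficientDataError(
            "insufficient_obs",
            f"need >= {config.min_obs} observations with "
            f">= {config.min_reads} reads, got {a.size}",
        )
    const = float(np.sum(_choose_term(a, n)))
    starts = list(extra_starts)
    if include_default_starts or not starts:
        starts += _null_starts(config)
    return _grouped_fit([(a, n)], starts, config, const)


def fit_alt_mixture(
    obs_hom,
    obs_het,
    config: FitConfig | None = None,
    null_fit: MixtureFit | None = None,
) -> MixtureFit:
    """Fit the genotype-dependent mixture (pi_hom, pi_het free).

    The start set always includes the null optimum (with both weights at
    pi_null), so the alternative log-likelihood can never fall below the
    null's.  If ``null_fit`` is omitted it is fitted internally.
    """
    config = config or FitConfig()
    groups, const = _prepare_groups([obs_hom, obs_het], ["hom", "het"], config)
    if null_fit is None:
        pooled = (
            np.concatenate([g[0] for g in groups]),
            np.concatenate([g[1] for g in groups]),
        )
        null_fit = fit_null_mixture(pooled, config)
    t_null = logit(_clip_pi(null_fit.pi))
    starts = [
        (np.log(null_fit.alpha1), np.log(null_fit.alpha2), t_null, t_null)
    ]
    for a1, a2, p in _DEFAULT_STARTS[: max(1, config.n_starts)]:
        starts.append((np.log(a1), np.log(a2), logit(p), logit(p)))
    return _grouped_fit(groups, starts, config, const)


def _prepare_groups(group_obs, names, config: FitConfig):
    groups = []
    for obs, name in zip(group_obs, names):
        a, n = _filter_counts(obs, config.min_reads)
        if a.size < config.min_group_n:
            raise InsufficientDataError(
                f"insufficient_{name}",
                f"group '{name}' has {a.size} observations with "
                f">= {config.min_reads} reads; need >= {config.min_group_n}",
            )
        groups.append((a, n))
    const = float(sum(np.sum(_choose_term(a, n)) for a, n in groups))
    return groups, const


def aiqtl_test(obs_hom, obs_het, config: FitConfig | None = None) -> AiqtlTestResult:
    """Likelihood-ratio test for a genotype-dependent mixing weight.

    Fits the shared-weight null on the pooled observations, the
    alternative with separate weights for the hom and het groups
    (initialized from the null optimum among other starts), then re-fits
    the null starting from the alternative optimum with the single weight
    set to the group-size-weighted average of (pi_hom, pi_het).  The test
    statistic 2 * (l_alt - l_null) is referred to chi-squared(1).
    """
    config = config or FitConfig()
    groups, const = _prepare_groups([obs_hom, obs_het], ["hom", "het"], config)
    (a_hom, n_hom), (a_het, n_het) = groups
    pooled = (np.concatenate([a_hom, a_het]), np.concatenate([n_hom, n_het]))
    null_fit = fit_null_mixture(pooled, config)
    alt_fit = fit_alt_mixture((a_hom, n_hom), (a_het, n_het), config, null_fit)
    # Reverse-direction start: re-optimize the null from the alternative
    # optimum, collapsing the two weights by their group sizes.
    w = a_hom.size / (a_hom.size + a_het.size)
    pi_bar = _clip_pi(w * alt_fit.pi_hom + (1.0 - w) * alt_fit.pi_het)
    null_refit = fit_null_mixture(
        pooled,
        config,
        extra_starts=[
            (np.log(alt_fit.alpha1), np.log(alt_fit.alpha2), logit(pi_bar))
        ],
        include_default_starts=False,
    )
    if null_refit.loglik > null_fit.loglik:
        null_fit = null_refit
    lrt = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
    p = float(chi2.sf(lrt, df=1))
    return AiqtlTestResult(
        lrt_stat=lrt,
        df=1,
        p_value=p,
        null_fit=null_fit,
        alt_fit=alt_fit,
        n_hom=int(a_hom.size),
        n_het=int(a_het.size),
    )


def aiqtl_test_groups(
    groups: dict[str, object], config: FitConfig | None = None
) -> AiqtlTestResult:
    """Generalized test with one mixing weight per genotype group.

    ``groups`` maps group labels (e.g. three genotype classes) to
    observations; the LRT has ``len(groups) - 1`` degrees of freedom.
    The two-group het/hom version is the default analysis; this variant
    supports a per-genotype parameterization.
    """
    config = config or FitConfig()
    names = list(groups)
    if len(names) < 2:
        raise InsufficientDataError("too_few_groups", "need >= 2 genotype groups")
    prepared, const = _prepare_groups([groups[k] for k in names], names, config)
    pooled = (
        np.concatenate([g[0] for g in prepared]),
        np.concatenate([g[1] for g in prepared]),
    )
    null_fit = fit_null_mixture(pooled, config)
    t_null = logit(_clip_pi(null_fit.pi))
    starts = [
        (np.log(null_fit.alpha1), np.log(null_fit.alpha2))
        + (t_null,) * len(prepared)
    ]
    for a1, a2, p in _DEFAULT_STARTS[: max(1, config.n_starts)]:
        starts.append((np.log(a1), np.log(a2)) + (logit(p),) * len(prepared))
    alt_fit = _grouped_fit(prepared, starts, config, const)
    sizes = np.array([g[0].size for g in prepared], dtype=float)
    pi_bar = _clip_pi(
        float(np.dot(sizes, alt_fit.pi_by_group) / sizes.sum())
    )
    null_refit = fit_null_mixture(
        pooled,
        config,
        extra_starts=[
            (np.log(alt_fit.alpha1), np.log(alt_fit.alpha2), logit(pi_bar))
        ],
        include_default_starts=False,
    )
    if null_refit.loglik > null_fit.loglik:
        null_fit = null_refit
    df = len(prepared) - 1
    lrt = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
    n_by = {k: g[0].size for k, g in zip(names, prepared)}
    return AiqtlTestResult(
        lrt_stat=lrt,
        df=df,
        p_value=float(chi2.sf(lrt, df=df)),
        null_fit=null_fit,
        alt_fit=alt_fit,
        n_hom=int(n_by.get("hom", 0)),
        n_het=int(n_by.get("het", 0)),
    )


def fit_sample_alpha(
    obs, config: FitConfig | None = None, sample_id: str | None = None
) -> SampleAlphaFit:
    """Maximum-likelihood single-alpha fit for one sample across genes.

    One-dimensional bounded optimization over log alpha; deterministic.
    A sample whose genes are all perfectly balanced drives alpha to the
    upper bound (and conversely for monoallelic expression); boundary
    hits are flagged rather than treated as errors.
    """
    config = config or FitConfig()
    if sample_id is None:
        sample_id = ""
        try:
            first = next(iter(obs))
            if isinstance(first, AseObservation):
                sample_id = first.sample_id
        except (TypeError, StopIteration):
            pass
    a, n = _filter_counts(obs, config.min_reads)
    if a.size < config.min_obs:
        raise InsufficientDataError(
            "insufficient_obs",
            f"need >= {config.min_obs} genes with >= {config.min_reads} reads, "
            f"got {a.size}",
        )
    const = float(np.sum(_choose_term(a, n)))
    lo, hi = np.log(config.alpha_bounds[0]), np.log(config.alpha_bounds[1])

    def neg_ll(la):
        return -float(np.sum(_kernel(a, n, np.exp(la))))

    res = minimize_scalar(
        neg_ll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    alpha = float(np.exp(res.x))
    # bounded golden-section stops short of the boundary; 1e-3 on the log
    # scale (0.1% in alpha) is well inside optimizer resolution
    at_bound = res.x <= lo + 1e-3 or res.x >= hi - 1e-3
    return SampleAlphaFit(
        sample_id=sample_id,
        alpha=alpha,
        n_obs=int(a.size),
        loglik=const - float(res.fun),
        at_bound=bool(at_bound),
    )
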