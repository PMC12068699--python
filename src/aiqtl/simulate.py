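"""Synthetic allele-specific count data under three simulation designs.

Three generative designs are provided, mirroring the scenarios the mixture
model must handle:

``two_negbin``
    Each haplotype's read count is an independent negative binomial; in
    heterozygotes at the regulatory variant the two haplotype means differ
    by a fold-change.  This design does *not* share the structure of the
    detection model, so it probes robustness to model misspecification.
    ``fold_change=1`` is a null design.

``negbin_sbb``
    The total allele-mapped read count is negative binomial and the
    A-allele count given the total is symmetric beta-binomial, with a
    smaller alpha (more imbalance) in heterozygotes.  ``alpha_het ==
    alpha_hom`` is a null design.

``trans``
    A trans-acting variant: the expression mean of *both* haplotypes
    scales with the alternative-allele dosage (a factor per allele), but
    the allelic split carries no genotype signal.  A calibrated cis test
    must not reject here, while depth-sensitive tests are fooled.

Negative binomials are parameterized by (mean, size) with variance
``mean + mean**2 / size``: small size means strong overdispersion, the
Poisson limit as size grows.

Randomness: each experiment uses a single integer seed; per-replicate
substreams are derived deterministically from (seed, replicate index), so
identical seeds give bit-identical replicate tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import AseObservation, DataError, Genotype, GenotypeClass
from .model import FAST_FIT, FitConfig, aiqtl_test

__all__ = [
    "SimConfig",
    "SimReplicate",
    "simulate_genotypes",
    "simulate_two_negbin",
    "simulate_negbin_sbb",
    "simulate_trans_eqtl",
    "run_experiment",
    "mixture_test_fn",
]

_DESIGNS = ("two_negbin", "negbin_sbb", "trans")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation scenario.

    negbin_mean is the mean of the *total* allele-mapped read count per
    sample (split across haplotypes where the design draws per-haplotype
    counts); 30 reads reflects a typical median for allele-specifically
    mapped RNA-seq coverage of a gene.
    """

    n_individuals: int = 670
    maf: float = 0.1
    negbin_mean: float = 30.0
    negbin_size: float = 100.0
    fold_change: float = 1.0
    alpha_hom: float = 100.0
    alpha_het: float = 100.0
    n_reps: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise DataError(f"maf must lie in (0, 0.5], got {self.maf}")
        if self.negbin_mean <= 0 or self.negbin_size <= 0:
            raise DataError("negative-binomial mean and size must be positive")
        if self.fold_change < 1.0:
            raise DataError("fold_change must be >= 1")
        if self.alpha_hom <= 0 or self.alpha_het <= 0:
            raise DataError("alpha parameters must be positive")


@dataclass(frozen=True)
class SimReplicate:
    """One simulated dataset plus its generating truth."""

    genotypes: list[GenotypeClass]
    observations: list[AseObservation]
    truth: str  # NULL, CIS or TRANS
    true_params: dict


def _rng_for(seed: int, rep: int | None = None):
    if rep is None:
        return np.random.default_rng(np.random.SeedSequence(seed))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))


def _nb_draw(rng, mean: float, size: float, n: int) -> np.ndarray:
    # numpy parameterizes by (n=size, p); p = size / (size + mean)
    return rng.negative_binomial(size, size / (size + mean), size=n)


def simulate_genotypes(
    n: int, maf: float, seed_or_rng: int | np.random.Generator
) -> list[GenotypeClass]:
    """Draw het/hom genotype classes under Hardy-Weinberg equilibrium.

    Each individual is heterozygous with probability 2*maf*(1-maf).
    """
    if not (0.0 < maf <= 0.5):
        raise DataError(f"maf must lie in (0, 0.5], got {maf}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else _rng_for(seed_or_rng)
    )
    p_het = 2.0 * maf * (1.0 - maf)
    het = rng.random(n) < p_het
    return [
        GenotypeClass(f"s{i:04d}", Genotype.HET if h else Genotype.HOM)
        for i, h in enumerate(het)
    ]


def _dosages(rng, n: int, maf: float) -> np.ndarray:
    """Alternative-allele dosages 0/1/2 under Hardy-Weinberg."""
    return rng.binomial(2, maf, size=n)


def _to_observations(samples, a, total) -> list[AseObservation]:
    # Individuals with zero allele-mapped reads cannot yield an observation;
    # they are dropped here and the read-depth filters handle the rest.
    return [
        AseObservation(s, int(ai), int(ti))
        for s, ai, ti in zip(samples, a, total)
        if ti >= 1
    ]


def simulate_two_negbin(
    genotypes: Sequence[GenotypeClass],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimReplicate:
    """Two independent negative-binomial haplotypes per individual.

    Heterozygotes' haplotype means are ``m`` and ``m * fold_change`` with
    ``m`` chosen so the expected total stays at ``negbin_mean``; which
    haplotype is elevated is random per individual (no consistency of the
    over-expressed allele across samples).  Homozygotes' haplotypes share
    the base mean.
    """
    config.validate()
    rng = rng or _rng_for(config.seed)
    n = len(genotypes)
    het = np.array([g.cls is Genotype.HET for g in genotypes])
    fc = config.fold_change
    base = config.negbin_mean / 2.0
    m_lo = np.where(het, config.negbin_mean / (1.0 + fc), base)
    m_hi = np.where(het, m_lo * fc, base)
    h1 = rng.negative_binomial(
        config.negbin_size, config.negbin_size / (config.negbin_size + m_lo)
    )
    h2 = rng.negative_binomial(
        config.negbin_size, config.negbin_size / (config.negbin_size + m_hi)
    )
    pick_h1 = rng.random(n) < 0.5
    a = np.where(pick_h1, h1, h2)
    total = h1 + h2
    samples = [g.sample_id for g in genotypes]
    return SimReplicate(
        genotypes=list(genotypes),
        observations=_to_observations(samples, a, total),
        truth="NULL" if fc == 1.0 else "CIS",
        true_params={"design": "two_negbin", **asdict(config)},
    )


def simulate_negbin_sbb(
    genotypes: Sequence[GenotypeClass],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimReplicate:
    """Negative-binomial total, symmetric beta-binomial allelic split.

    The split uses ``alpha_het`` for heterozygotes and ``alpha_hom`` for
    homozygotes; the more highly expressed allele is automatically random
    because the beta is symmetric.  Equal alphas give a null design.
    """
    config.validate()
    rng = rng or _rng_for(config.seed)
    n = len(genotypes)
    het = np.array([g.cls is Genotype.HET for g in genotypes])
    total = _nb_draw(rng, config.negbin_mean, config.negbin_size, n)
    alpha = np.where(het, config.alpha_het, config.alpha_hom)
    p = rng.beta(alpha, alpha)
    a = rng.binomial(total, p)
    samples = [g.sample_id for g in genotypes]
    return SimReplicate(
        genotypes=list(genotypes),
        observations=_to_observations(samples, a, total),
        truth="NULL" if config.alpha_het == config.alpha_hom else "CIS",
        true_params={"design": "negbin_sbb", **asdict(config)},
    )


def simulate_trans_eqtl(
    genotypes_or_n,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimReplicate:
    """A trans-acting eQTL: expression scales with dosage, split stays balanced.

    Three-class genotypes are drawn internally (the expression mean needs
    the alternative-allele dosage); each haplotype's reads are an
    independent negative binomial with mean ``(negbin_mean / 2) * fc**d``
    for dosage ``d`` (log-additive dosage model), so the alt/alt to
    ref/ref expression ratio is ``fc**2``.  Output genotypes collapse to
    het/hom for testing.  A correct cis test must stay at its nominal
    level here.
    """
    config.validate()
    rng = rng or _rng_for(config.seed)
    if isinstance(genotypes_or_n, int):
        n = genotypes_or_n
        d = _dosages(rng, n, config.maf)
        samples = [f"s{i:04d}" for i in range(n)]
    else:
        # honor supplied het/hom classes: hets get dosage 1, homs are
        # assigned 0 or 2 by the conditional HWE frequencies
        classes = list(genotypes_or_n)
        n = len(classes)
        samples = [g.sample_id for g in classes]
        p_aa = config.maf**2 / (config.maf**2 + (1 - config.maf) ** 2)
        d = np.array(
            [
                1
                if g.cls is Genotype.HET
                else (2 if rng.random() < p_aa else 0)
                for g in classes
            ]
        )
    fc = config.fold_change if config.fold_change > 1.0 else 1.5
    mean_hap = (config.negbin_mean / 2.0) * fc**d
    h1 = rng.negative_binomial(
        config.negbin_size, config.negbin_size / (config.negbin_size + mean_hap)
    )
    h2 = rng.negative_binomial(
        config.negbin_size, config.negbin_size / (config.negbin_size + mean_hap)
    )
    pick_h1 = rng.random(n) < 0.5
    a = np.where(pick_h1, h1, h2)
    total = h1 + h2
    genotypes = [
        GenotypeClass(s, Genotype.HET if di == 1 else Genotype.HOM)
        for s, di in zip(samples, d)
    ]
    return SimReplicate(
        genotypes=genotypes,
        observations=_to_observations(samples, a, total),
        truth="TRANS",
        true_params={
            "design": "trans",
            "dosage_model": "log_additive",
            "per_allele_factor": fc,
            "dosages": d.tolist(),
            **asdict(config),
        },
    )


# ---------------------------------------------------------------------------
# Experiment harness


def _simulate(design: str, config: SimConfig, rng) -> SimReplicate:
    if design == "two_negbin":
        g = simulate_genotypes(config.n_individuals, config.maf, rng)
        return simulate_two_negbin(g, config, rng)
    if design == "negbin_sbb":
        g = simulate_genotypes(config.n_individuals, config.maf, rng)
        return simulate_negbin_sbb(g, config, rng)
    if design == "trans":
        return simulate_trans_eqtl(config.n_individuals, config, rng)
    raise DataError(f"unknown design {design!r}; expected one of {_DESIGNS}")


def simulate_replicate(design: str, config: SimConfig, rep: int = 0) -> SimReplicate:
    """Generate replicate ``rep`` of a design (deterministic substream)."""
    return _simulate(design, config, _rng_for(config.seed, rep))


def split_replicate(rep: SimReplicate, min_reads: int = 2):
    """Split a replicate's observations into (hom, het) count arrays."""
    cls = {g.sample_id: g.cls for g in rep.genotypes}
    hom_a, hom_n, het_a, het_n = [], [], [], []
    for o in rep.observations:
        if o.total_count < min_reads:
            continue
        if cls[o.sample_id] is Genotype.HET:
            het_a.append(o.a_count)
            het_n.append(o.total_count)
        else:
            hom_a.append(o.a_count)
            hom_n.append(o.total_count)
    return (
        (np.array(hom_a, dtype=np.int64), np.array(hom_n, dtype=np.int64)),
        (np.array(het_a, dtype=np.int64), np.array(het_n, dtype=np.int64)),
    )


def mixture_test_fn(config: FitConfig = FAST_FIT) -> Callable:
    """Adapter returning the mixture-model p-value for the harness."""

    def test(obs_hom, obs_het) -> float:
        return aiqtl_test(obs_hom, obs_het, config).p_value

    test.__name__ = "mixture"
    return test


def run_experiment(
    design: str,
    grid: Iterable[SimConfig],
    test_fns: Sequence[Callable],
    level: float = 0.05,
    fit_config: FitConfig = FAST_FIT,
) -> pd.DataFrame:
    """Monte-Carlo rejection rates for each grid point and test.

    Returns a tidy table with one row per (grid point, test): the
    fraction of replicates with p < ``level``, its Monte-Carlo standard
    error, and the number of replicates excluded because a test could not
    be run (small groups); exclusions are counted, never silently dropped.
    """
    rows = []
    for config in grid:
        config.validate()
        if config.n_reps < 1:
            raise DataError("n_reps must be >= 1")
        pvals: dict[str, list[float]] = {f.__name__: [] for f in test_fns}
        failures: dict[str, int] = {f.__name__: 0 for f in test_fns}
        for rep in range(config.n_reps):
            replicate = _simulate(design, config, _rng_for(config.seed, rep))
            (hom, het) = split_replicate(replicate, fit_config.min_reads)
            for f in test_fns:
                try:
                    pvals[f.__name__].append(float(f(hom, het)))
                except Exception:
                    failures[f.__name__] += 1
        for f in test_fns:
            name = f.__name__
            p = np.asarray(pvals[name])
            n_ok = p.size
            rate = float(np.mean(p < level)) if n_ok else float("nan")
            se = float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else float("nan")
            rows.append(
                {
                    "design": design,
                    "test": name,
                    "level": level,
                    "n_reps": config.n_reps,
                    "n_ok": n_ok,
                    "n_failed": failures[name],
                    "rejection_rate": rate,
                    "mc_se": se,
                    **{
                        k: v
                        for k, v in asdict(config).items()
                        if k not in ("n_reps",)
                    },
                }
            )
    return pd.DataFrame(rows)


def collect_test_stats(
    design: str,
    config: SimConfig,
    fit_config: FitConfig = FAST_FIT,
) -> pd.DataFrame:
    """Mixture-test LRT statistics and p-values across replicates.

    One row per replicate; used for null-calibration QQ analysis.
    """
    rows = []
    for rep in range(config.n_reps):
        replicate = _simulate(design, config, _rng_for(config.seed, rep))
        hom, het = split_replicate(replicate, fit_config.min_reads)
        res = aiqtl_test(hom, het, fit_config)
        rows.append({"rep": rep, "lrt_stat": res.lrt_stat, "p_value": res.p_value})
    return pd.DataFrame(rows)
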