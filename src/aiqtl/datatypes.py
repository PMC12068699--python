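"""Core domain types shared across the package.

Allele-specific expression data enter the model as pairs of counts per
(sample, gene): the number of reads assigned to an arbitrarily labelled
"A" allele and the total number of allele-specifically mapped reads.
Because the A label is arbitrary and need not agree between samples, every
statistic in this package is invariant under flipping ``a_count`` to
``total_count - a_count`` in any subset of observations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AseObservation",
    "GenotypeClass",
    "Genotype",
    "as_count_arrays",
    "DataError",
    "InsufficientDataError",
    "FitError",
]


class DataError(ValueError):
    """Invalid input data (malformed counts, bad parameter domain...)."""


class InsufficientDataError(DataError):
    """A test or fit cannot be run because a group or dataset is too small.

    ``reason`` is a short machine-readable code, e.g. ``insufficient_het``.
    """

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or reason)


class FitError(RuntimeError):
    """Numerical optimization failed to produce a finite likelihood."""


class Genotype(enum.Enum):
    """Genotype class at a candidate regulatory variant.

    Both homozygote classes (ref/ref and alt/alt) are pooled into ``HOM``:
    under the default parameterization only heterozygosity at the variant
    is expected to change the extent of allelic imbalance of the gene.
    """

    HET = "het"
    HOM = "hom"


@dataclass(frozen=True)
class AseObservation:
    """Allele-specific read counts for one (sample, gene) pair."""

    sample_id: str
    a_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.total_count < 1:
            raise DataError(
                f"total_count must be >= 1, got {self.total_count} "
                f"for sample {self.sample_id!r}"
            )
        if not (0 <= self.a_count <= self.total_count):
            raise DataError(
                f"a_count must lie in [0, total_count], got "
                f"{self.a_count}/{self.total_count} for sample {self.sample_id!r}"
            )

    @property
    def proportion(self) -> float:
        return self.a_count / self.total_count


@dataclass(frozen=True)
class GenotypeClass:
    """Per-sample genotype class at one candidate variant."""

    sample_id: str
    cls: Genotype


def as_count_arrays(obs) -> tuple[np.ndarray, np.ndarray]:
    """Coerce observations to integer count arrays ``(a, n)``.

    Accepts a sequence of :class:`AseObservation`, a ``(a, n)`` pair of
    array-likes, or a 2-column array of ``[a_count, total_count]`` rows.
    """
    if isinstance(obs, tuple) and len(obs) == 2:
        a = np.asarray(obs[0], dtype=np.int64)
        n = np.asarray(obs[1], dtype=np.int64)
    else:
        arr = np.asarray(obs)
        if arr.dtype == object or arr.ndim == 1 and arr.size and isinstance(
            arr.flat[0], AseObservation
        ):
            seq: Sequence[AseObservation] = list(obs)
            a = np.fromiter((o.a_count for o in seq), dtype=np.int64, count=len(seq))
            n = np.fromiter(
                (o.total_count for o in seq), dtype=np.int64, count=len(seq)
            )
        elif arr.ndim == 2 and arr.shape[1] == 2:
            a = arr[:, 0].astype(np.int64)
            n = arr[:, 1].astype(np.int64)
        elif arr.size == 0:
            a = np.empty(0, dtype=np.int64)
            n = np.empty(0, dtype=np.int64)
        else:
            raise DataError("cannot interpret observations; pass (a, n) arrays")
    if a.shape != n.shape:
        raise DataError("a and n must have the same length")
    if np.any(n < 1):
        raise DataError("total_count must be >= 1 for every observation")
    if np.any((a < 0) | (a > n)):
        raise DataError("a_count must lie in [0, total_count] for every observation")
    return a, n


def split_by_genotype(
    observations: Iterable[AseObservation],
    genotypes: Iterable[GenotypeClass],
) -> tuple[list[AseObservation], list[AseObservation]]:
    """Partition observations into (hom, het) lists by sample genotype.

    Samples without a genotype record are dropped.
    """
    cls_by_sample = {g.sample_id: g.cls for g in genotypes}
    hom: list[AseObservation] = []
    het: list[AseObservation] = []
    for o in observations:
        cls = cls_by_sample.get(o.sample_id)
        if cls is Genotype.HOM:
            hom.append(o)
        elif cls is Genotype.HET:
            het.append(o)
    return hom, het
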