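"""File formats, run configuration and example-fixture generation.

All tables are UTF-8, tab-separated with a header row, '.' for missing
values.  VCF positions follow the standard 1-based convention; internal
coordinates are 0-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import DataError, Genotype, GenotypeClass
from .model import FitConfig
from .simulate import SimConfig, simulate_genotypes, simulate_negbin_sbb, simulate_trans_eqtl

logger = logging.getLogger("aiqtl")

__all__ = [
    "RunConfig",
    "read_counts",
    "write_counts",
    "read_genotype_classes",
    "genotypes_to_frame",
    "make_fixture",
]

_COUNT_COLS = ["sample_id", "gene_id", "a_count", "total_count"]


@dataclass(frozen=True)
class RunConfig:
    """Aggregate configuration for a scan run (round-trippable to YAML)."""

    min_reads: int = 2
    min_obs: int = 20
    min_group_n: int = 10
    alpha_bounds: tuple[float, float] = (1e-3, 1e6)
    n_starts: int = 6
    detection_level: float = 0.01
    adjustment: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.detection_level < 1.0):
            raise DataError("detection_level must lie in (0, 1)")
        if min(self.min_reads, self.min_obs, self.min_group_n, self.n_starts) <= 0:
            raise DataError("thresholds must be positive")
        if self.adjustment not in ("none", "holm", "bh"):
            raise DataError(f"unknown adjustment {self.adjustment!r}")

    @property
    def fit_config(self) -> FitConfig:
        return FitConfig(
            min_reads=self.min_reads,
            min_obs=self.min_obs,
            min_group_n=self.min_group_n,
            alpha_bounds=tuple(self.alpha_bounds),
            n_starts=self.n_starts,
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["alpha_bounds"] = list(d["alpha_bounds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "alpha_bounds" in d:
            d["alpha_bounds"] = tuple(d["alpha_bounds"])
        return cls(**d)


def read_counts(path, site_policy: str = "max_coverage") -> pd.DataFrame:
    """Read an allele-specific counts table.

    Expected columns: sample_id, gene_id, a_count, total_count, and
    optionally site_id when counts are reported per transcribed SNP
    rather than per gene.  With multiple sites per (sample, gene),
    ``site_policy="max_coverage"`` keeps the site with the largest total
    count — summing sites could double-count fragments, and a
    haplotype-aware sum would need phasing, which this method avoids —
    while ``"error_on_multi"`` refuses such input.
    """
    if site_policy not in ("max_coverage", "error_on_multi"):
        raise DataError(f"unknown site_policy {site_policy!r}")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str}, na_values=["."])
    missing = [c for c in _COUNT_COLS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if pd.isna(row.a_count) or pd.isna(row.total_count):
            raise DataError(f"{path}: line {i}: missing count")
        if row.total_count < 1 or not (0 <= row.a_count <= row.total_count):
            raise DataError(
                f"{path}: line {i}: invalid counts "
                f"a={row.a_count} total={row.total_count}"
            )
    df["a_count"] = df["a_count"].astype(np.int64)
    df["total_count"] = df["total_count"].astype(np.int64)
    key = ["sample_id", "gene_id"] + (["site_id"] if "site_id" in df.columns else [])
    dup = df.duplicated(subset=key)
    if dup.any():
        raise DataError(
            f"{path}: duplicate rows for {key}: lines "
            f"{[i + 2 for i in df.index[dup][:5].tolist()]}"
        )
    if "site_id" in df.columns:
        multi = df.duplicated(subset=["sample_id", "gene_id"], keep=False)
        if multi.any():
            if site_policy == "error_on_multi":
                raise DataError(
                    f"{path}: multiple sites per (sample, gene) present "
                    "and site_policy='error_on_multi'"
                )
            before = len(df)
            df = (
                df.sort_values(
                    ["sample_id", "gene_id", "total_count", "site_id"],
                    ascending=[True, True, False, True],
                    kind="mergesort",
                )
                .groupby(["sample_id", "gene_id"], sort=False)
                .head(1)
                .reset_index(drop=True)
            )
            logger.info(
                "read_counts: max_coverage policy dropped %d of %d site rows",
                before - len(df),
                before,
            )
    return df.reset_index(drop=True)


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def _classify_gt(allele_indices) -> Genotype | None:
    alleles = [a for a in allele_indices if a is not None]
    if len(alleles) != 2:
        return None
    if any(a not in (0, 1) for a in alleles):
        return None  # only the designated ref/alt pair is usable
    return Genotype.HET if alleles[0] != alleles[1] else Genotype.HOM


def read_genotype_classes(path, variant_id: str | None = None) -> list[GenotypeClass]:
    """Read per-sample het/hom classes from a VCF or a TSV.

    VCF: the record matching ``variant_id`` (by ID, or the sole record if
    the file has one) supplies GT fields; 0/1 and phased equivalents are
    HET, 0/0 and 1/1 HOM.  Samples with missing GT, or with alleles other
    than the designated ref/alt pair at multi-allelic sites, are excluded
    (logged).  TSV: columns sample_id plus either ``class`` (het/hom) or
    ``dosage`` (0/1/2).
    """
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
        return _read_vcf_classes(path, variant_id)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."])
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: missing sample_id column")
    if "variant_id" in df.columns and variant_id is not None:
        df = df[df["variant_id"] == variant_id]
        if df.empty:
            raise DataError(f"{path}: variant {variant_id!r} not found")
    if "class" in df.columns and "cls" not in df.columns:
        df = df.rename(columns={"class": "cls"})
    out: list[GenotypeClass] = []
    n_missing = 0
    if "cls" in df.columns:
        for sample, c in zip(df["sample_id"], df["cls"]):
            if pd.isna(c):
                n_missing += 1
                continue
            c = c.lower()
            if c not in ("het", "hom"):
                raise DataError(f"{path}: invalid class {c!r}")
            out.append(
                GenotypeClass(sample, Genotype.HET if c == "het" else Genotype.HOM)
            )
    elif "dosage" in df.columns:
        for sample, dval in zip(df["sample_id"], df["dosage"]):
            if pd.isna(dval):
                n_missing += 1
                continue
            d = int(dval)
            if d not in (0, 1, 2):
                raise DataError(f"{path}: invalid dosage {d}")
            out.append(
                GenotypeClass(sample, Genotype.HET if d == 1 else Genotype.HOM)
            )
    else:
        raise DataError(f"{path}: need a 'class'/'cls' or 'dosage' column")
    if not out:
        raise DataError(f"{path}: no usable genotype records")
    if n_missing:
        logger.info("read_genotype_classes: excluded %d samples with missing genotype", n_missing)
    return out


def _read_vcf_classes(path, variant_id):
    import pysam

    out: list[GenotypeClass] = []
    n_excluded = 0
    with pysam.VariantFile(str(path)) as vcf:
        record = None
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if variant_id is None or rec.id == variant_id:
                record = rec
                break
        if record is None:
            raise DataError(f"{path}: variant {variant_id!r} not found")
        for sample, call in record.samples.items():
            cls = _classify_gt(call.allele_indices)
            if cls is None:
                n_excluded += 1
                continue
            out.append(GenotypeClass(sample, cls))
    if not out:
        raise DataError(f"{path}: all genotypes missing or unusable")
    if n_excluded:
        logger.info(
            "read_genotype_classes: excluded %d samples (missing GT or off-pair alleles)",
            n_excluded,
        )
    return out


def genotypes_to_frame(genotypes, variant_id: str) -> pd.DataFrame:
    """GenotypeClass list -> scan-ready frame (sample_id, variant_id, cls)."""
    return pd.DataFrame(
        {
            "sample_id": [g.sample_id for g in genotypes],
            "variant_id": variant_id,
            "cls": [g.cls.value for g in genotypes],
        }
    )


_FIXTURE_KINDS = {
    # kind -> (design, SimConfig overrides, truth label)
    "cis_strong": ("negbin_sbb", dict(alpha_het=5.0, maf=0.3), "CIS"),
    "cis_moderate": ("negbin_sbb", dict(alpha_het=20.0, maf=0.3), "CIS"),
    "null": ("negbin_sbb", dict(alpha_het=100.0, maf=0.3), "NULL"),
    "trans": ("trans", dict(fold_change=1.5, maf=0.1), "TRANS"),
}


def make_fixture(kind: str, seed: int, outdir) -> dict[str, Path]:
    """Write a small on-disk example dataset with recorded ground truth.

    Produces counts.tsv, genotypes.tsv, pairs.tsv and truth.json for one
    gene-variant pair simulated under the requested design (300
    individuals).  Used by the documentation and as CLI test input.
    """
    if kind not in _FIXTURE_KINDS:
        raise DataError(f"unknown fixture kind {kind!r}; choose from {sorted(_FIXTURE_KINDS)}")
    design, overrides, truth = _FIXTURE_KINDS[kind]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = SimConfig(n_individuals=300, seed=seed, **overrides)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if design == "trans":
        rep = simulate_trans_eqtl(config.n_individuals, config, rng)
    else:
        genotypes = simulate_genotypes(config.n_individuals, config.maf, rng)
        rep = simulate_negbin_sbb(genotypes, config, rng)
    gene, variant = "gene1", "var1"
    counts = pd.DataFrame(
        {
            "sample_id": [o.sample_id for o in rep.observations],
            "gene_id": gene,
            "a_count": [o.a_count for o in rep.observations],
            "total_count": [o.total_count for o in rep.observations],
        }
    )
    geno = genotypes_to_frame(rep.genotypes, variant)
    informative = counts["total_count"] >= 2
    pairs = pd.DataFrame(
        [
            {
                "variant_id": variant,
                "gene_id": gene,
                "tss_distance": 10_000,
                "maf": config.maf,
                "eqtl_log10_p": -10.0,
                "n_informative_samples": int(informative.sum()),
                "median_reads": float(counts.loc[informative, "total_count"].median()),
            }
        ]
    )
    paths = {
        "counts": outdir / "counts.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "pairs": outdir / "pairs.tsv",
        "truth": outdir / "truth.json",
    }
    write_counts(counts, paths["counts"])
    geno.to_csv(paths["genotypes"], sep="\t", index=False)
    pairs.to_csv(paths["pairs"], sep="\t", index=False)
    paths["truth"].write_text(
        json.dumps({"kind": kind, "truth": truth, "seed": seed, **rep.true_params}, indent=2)
    )
    return paths
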