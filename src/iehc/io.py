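"""File readers/writers: TSV dialects, PLINK bed/bim/fam, run configuration.

TSV conventions: tab-separated with a header row; '.' or 'NA' mark missing
dosages.  The dosage file has sample ids in the first column and SNP ids as
the remaining header cells; allele metadata may ride along in optional
``#effect_alleles`` / ``#other_alleles`` comment lines (tab-separated, one
cell per SNP).  PLINK input is the standard binary triple: .bim / .fam via
pandas, the SNP-major 2-bit .bed decoded here (the count convention is
copies of the A1 allele, taken as the effect allele).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from iehc.cox import SurvivalDataset
from iehc.pipeline import GeneSet, GenotypeMatrix, IEHCConfig, WeightSet

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_genotypes",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_plink",
    "write_plink",
    "read_phenotype",
    "read_weights",
    "read_genesets",
    "resolve_regions",
    "write_results",
    "ParseError",
]

_MISSING = {".", "NA", "nan", ""}
_VALID_ALLELES = {"A", "C", "G", "T"}


class ParseError(ValueError):
    """Malformed input file; the message carries the offending location."""


@dataclass
class RunConfig:
    """YAML-loadable run configuration with QC and test settings."""

    genotypes: str | None = None
    phenotype: str | None = None
    weights: str | None = None
    genesets: str | None = None
    output_dir: str = "."
    seed: int = 0
    maf_min: float = 0.01
    miss_max: float = 0.05
    hwe_alpha: float = 1e-4
    rho_grid: tuple = None
    alpha: float = 0.05
    fdr_level: float = 0.1
    standardize_covariates: bool = True
    ties: str = "efron"
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def pipeline_config(self) -> IEHCConfig:
        kw = dict(maf_min=self.maf_min, miss_max=self.miss_max,
                  hwe_alpha=self.hwe_alpha, standardize_covariates=self.standardize_covariates,
                  ties=self.ties, alpha=self.alpha, fdr_level=self.fdr_level)
        if self.rho_grid is not None:
            kw["rho_grid"] = tuple(self.rho_grid)
        return IEHCConfig(**kw)

    def digest(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def read_genotypes(path: str, fmt: str | None = None) -> GenotypeMatrix:
    """Load genotypes from a TSV dosage file or a PLINK prefix."""
    p = Path(path)
    if fmt == "plink" or (fmt is None and (p.with_suffix(".bed").exists() or p.suffix == ".bed")):
        return read_plink(str(p.with_suffix("")) if p.suffix == ".bed" else str(p))
    return read_dosage_tsv(path)


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    ea = oa = None
    header = None
    rows, sample_ids = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if line.startswith("#effect_alleles"):
                ea = np.asarray(cells[1:], dtype=object)
                continue
            if line.startswith("#other_alleles"):
                oa = np.asarray(cells[1:], dtype=object)
                continue
            if line.startswith("#"):
                continue
            if header is None:
                header = cells
                continue
            if len(cells) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(cells)}")
            sample_ids.append(cells[0])
            row = []
            for k, c in enumerate(cells[1:], start=1):
                if c in _MISSING:
                    row.append(np.nan)
                else:
                    try:
                        v = float(c)
                    except ValueError:
                        raise ParseError(f"{path}:{lineno}: bad dosage {c!r}") from None
                    if v not in (0.0, 1.0, 2.0):
                        raise ParseError(f"{path}:{lineno}: dosage must be 0/1/2, got {c}")
                    row.append(v)
            rows.append(row)
    if header is None or not rows:
        raise ParseError(f"{path}: no data rows")
    snp_ids = np.asarray(header[1:], dtype=object)
    for arr, name in ((ea, "#effect_alleles"), (oa, "#other_alleles")):
        if arr is not None and len(arr) != len(snp_ids):
            raise ParseError(f"{path}: {name} length does not match SNP count")
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample ids")
    return GenotypeMatrix(
        sample_ids=np.asarray(sample_ids, dtype=object),
        snp_ids=snp_ids,
        dosages=np.asarray(rows, dtype=float),
        effect_allele=ea,
        other_allele=oa,
    )


def write_dosage_tsv(G: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        if G.effect_allele is not None:
            fh.write("#effect_alleles\t" + "\t".join(map(str, G.effect_allele)) + "\n")
        if G.other_allele is not None:
            fh.write("#other_alleles\t" + "\t".join(map(str, G.other_allele)) + "\n")
        fh.write("sample_id\t" + "\t".join(map(str, G.snp_ids)) + "\n")
        for i, sid in enumerate(G.sample_ids):
            cells = ["." if np.isnan(v) else str(int(v)) for v in G.dosages[i]]
            fh.write(str(sid) + "\t" + "\t".join(cells) + "\n")


_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes in SNP-major .bed: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# Dosage = copies of A1 (the effect allele).
_BED_DECODE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}


def read_plink(prefix: str) -> GenotypeMatrix:
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"chrom": str})
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"])
    raw = Path(f"{prefix}.bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ParseError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
    n, m = len(fam), len(bim)
    stride = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != stride * m:
        raise ParseError(f"{prefix}.bed: size does not match {n} samples x {m} SNPs")
    codes = body.reshape(m, stride)
    # unpack two-bit fields, little-endian within each byte
    shifts = np.arange(4) * 2
    two_bit = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    two_bit = two_bit.reshape(m, stride * 4)[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[two_bit].T  # n x m
    return GenotypeMatrix(
        sample_ids=fam["iid"].to_numpy(dtype=object),
        snp_ids=bim["snp"].to_numpy(dtype=object),
        dosages=dosages,
        effect_allele=bim["a1"].to_numpy(dtype=object),
        other_allele=bim["a2"].to_numpy(dtype=object),
    )


def write_plink(G: GenotypeMatrix, prefix: str, positions=None, chrom="1") -> None:
    """Write the bed/bim/fam triple (test and interchange helper)."""
    n, m = G.n, G.n_snps
    with open(f"{prefix}.fam", "w") as fh:
        for sid in G.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    ea = G.effect_allele if G.effect_allele is not None else ["A"] * m
    oa = G.other_allele if G.other_allele is not None else ["G"] * m
    pos = positions if positions is not None else (np.arange(m) + 1) * 1000
    with open(f"{prefix}.bim", "w") as fh:
        for j in range(m):
            fh.write(f"{chrom}\t{G.snp_ids[j]}\t0\t{pos[j]}\t{ea[j]}\t{oa[j]}\n")
    stride = (n + 3) // 4
    out = np.zeros((m, stride), dtype=np.uint8)
    code_of = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    for j in range(m):
        for i in range(n):
            v = G.dosages[i, j]
            code = 0b01 if np.isnan(v) else code_of[float(v)]
            out[j, i // 4] |= code << ((i % 4) * 2)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def read_phenotype(path: str) -> SurvivalDataset:
    """id, time, status, then covariates; validation errors name the row."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "time", "status"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: header must contain {sorted(required)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    for idx, row in df.iterrows():
        if not row["time"] > 0:
            raise ParseError(f"{path}: row {idx + 2}: non-positive time {row['time']}")
        if row["status"] not in (0, 1):
            raise ParseError(f"{path}: row {idx + 2}: status must be 0/1, got {row['status']}")
    covs = [c for c in df.columns if c not in required]
    X = df[covs].to_numpy(dtype=float) if covs else np.empty((len(df), 0))
    if covs and np.isnan(X).any():
        raise ParseError(f"{path}: missing covariate values")
    return SurvivalDataset(
        subject_id=df["id"].to_numpy(dtype=object),
        time=df["time"].to_numpy(dtype=float),
        status=df["status"].to_numpy(dtype=int),
        covariates=X,
        covariate_names=covs,
    )


def read_weights(path: str) -> dict[str, WeightSet]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["gene", "snp", "effect_allele", "other_allele", "beta"]
    if not set(required) <= set(df.columns):
        raise ParseError(f"{path}: header must contain {required}")
    for idx, row in df.iterrows():
        for col in ("effect_allele", "other_allele"):
            if str(row[col]) not in _VALID_ALLELES:
                raise ParseError(
                    f"{path}: line {idx + 2}: invalid allele {row[col]!r} (must be A/C/G/T)")
        if not np.isfinite(row["beta"]):
            raise ParseError(f"{path}: line {idx + 2}: non-finite beta")
    out = {}
    for gene, grp in df.groupby("gene", sort=False):
        if grp["snp"].duplicated().any():
            raise ParseError(f"{path}: duplicate SNP in gene {gene}")
        out[str(gene)] = WeightSet(
            gene=str(gene),
            snp_ids=grp["snp"].to_numpy(dtype=object),
            beta=grp["beta"].to_numpy(dtype=float),
            effect_allele=grp["effect_allele"].to_numpy(dtype=object),
            other_allele=grp["other_allele"].to_numpy(dtype=object),
        )
    return out


def read_genesets(path: str) -> list[GeneSet]:
    """Gene sets as (gene, snp) pairs or (gene, chrom, start, end) regions."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if {"gene", "snp"} <= set(df.columns):
        return [
            GeneSet(gene=str(g), snp_ids=grp["snp"].to_numpy(dtype=object))
            for g, grp in df.groupby("gene", sort=False)
        ]
    if {"gene", "chrom", "start", "end"} <= set(df.columns):
        out = []
        for idx, row in df.iterrows():
            if row["end"] < row["start"]:
                raise ParseError(f"{path}: row {idx + 2}: end < start")
            out.append(GeneSet(gene=str(row["gene"]), chrom=str(row["chrom"]),
                               start=int(row["start"]), end=int(row["end"])))
        return out
    raise ParseError(f"{path}: need columns (gene, snp) or (gene, chrom, start, end)")


def resolve_regions(genesets: list[GeneSet], bim: pd.DataFrame) -> list[GeneSet]:
    """Fill region-defined gene sets with the SNP ids inside [start, end].

    Coordinates are 1-based inclusive; explicit SNP-id membership takes
    precedence over region overlap.
    """
    out = []
    for gs in genesets:
        if gs.snp_ids.size or gs.chrom is None:
            out.append(gs)
            continue
        hit = bim[(bim["chrom"].astype(str) == gs.chrom)
                  & (bim["pos"] >= gs.start) & (bim["pos"] <= gs.end)]
        out.append(GeneSet(gene=gs.gene, snp_ids=hit["snp"].to_numpy(dtype=object),
                           chrom=gs.chrom, start=gs.start, end=gs.end))
    return out


def write_results(df: pd.DataFrame, path: str, config: RunConfig | None = None) -> None:
    """Results TSV with a reproducibility comment header."""
    from iehc import __version__

    with open(path, "w") as fh:
        fh.write(f"#iehc_version={__version__}\tschema=1")
        if config is not None:
            fh.write(f"\tseed={config.seed}\tconfig_hash={config.digest()}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
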