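"""Genotype/phenotype file formats, SNP quality control and imputation.

Gene content is coded 0/1/2 (copies of the counted allele) with ``NaN`` for
missing calls.  All base-pair positions are 1-based; chromosomes are string
labels.  The QC filters implemented here are the two marker filters commonly
applied to SNP-chip data before building a genomic relationship matrix:
minor allele frequency (MAF) and per-SNP call rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QcReport",
    "read_genotypes",
    "write_genotypes",
    "read_snp_map",
    "write_snp_map",
    "read_pedigree_frame",
    "read_phenotypes",
    "write_phenotypes",
    "compute_maf",
    "filter_snps",
    "impute_missing",
    "log_transform",
]

_ALLOWED_CODES = (0.0, 1.0, 2.0)


@dataclass
class GenotypeMatrix:
    """Animals x SNPs gene-content matrix.

    ``gene_content[i, j]`` is the number of copies (0, 1 or 2) of the counted
    allele of SNP ``j`` carried by animal ``i``; missing calls are ``NaN``.
    """

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    gene_content: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.gene_content = np.asarray(self.gene_content, dtype=float)
        n, m = self.gene_content.shape
        if n != self.animal_ids.size:
            raise ValueError(
                f"gene_content has {n} rows but {self.animal_ids.size} animal ids"
            )
        if m != self.snp_ids.size:
            raise ValueError(
                f"gene_content has {m} columns but {self.snp_ids.size} snp ids"
            )
        if pd.unique(self.animal_ids).size != self.animal_ids.size:
            raise ValueError("duplicated animal ids")
        if pd.unique(self.snp_ids).size != self.snp_ids.size:
            raise ValueError("duplicated snp ids")
        vals = self.gene_content[~np.isnan(self.gene_content)]
        bad = ~np.isin(vals, _ALLOWED_CODES)
        # continuous dosages (post mean-imputation) are tolerated in [0, 2]
        if np.any((vals < 0) | (vals > 2)):
            raise ValueError("gene content outside [0, 2]")
        del bad

    @property
    def n_animals(self) -> int:
        return self.gene_content.shape[0]

    @property
    def n_snps(self) -> int:
        return self.gene_content.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.gene_content).any())

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.animal_ids.copy(), self.snp_ids[mask], self.gene_content[:, mask]
        )


@dataclass
class QcReport:
    """Bookkeeping of the SNP quality-control step.

    Removal reasons are disjoint: the MAF test is applied first, so a SNP
    failing both filters is counted under ``n_removed_maf``.
    """

    n_input_snps: int
    n_removed_maf: int
    n_removed_callrate: int
    n_retained: int
    maf_min: float
    callrate_min: float
    per_snp: pd.DataFrame = field(repr=False)
    notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        total = self.n_removed_maf + self.n_removed_callrate + self.n_retained
        if total != self.n_input_snps:
            raise ValueError("QC counts do not add up")


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_genotypes(geno: GenotypeMatrix, path, dialect: str = "tsv") -> None:
    """Write genotypes as TSV (animals x SNPs) or PLINK .raw-style text."""
    path = Path(path)
    codes = geno.gene_content
    is_int = np.all(np.isnan(codes) | np.isin(codes, _ALLOWED_CODES))

    def fmt(v: float) -> str:
        if np.isnan(v):
            return "NA"
        return str(int(v)) if is_int else repr(float(v))

    if dialect == "tsv":
        with path.open("w") as fh:
            fh.write("animal\t" + "\t".join(map(str, geno.snp_ids)) + "\n")
            for i, aid in enumerate(geno.animal_ids):
                fh.write(str(aid) + "\t" + "\t".join(fmt(v) for v in codes[i]) + "\n")
    elif dialect == "plink_raw":
        header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        header += [f"{s}_A" for s in geno.snp_ids]
        with path.open("w") as fh:
            fh.write(" ".join(header) + "\n")
            for i, aid in enumerate(geno.animal_ids):
                row = [str(aid), str(aid), "0", "0", "0", "-9"]
                row += [fmt(v) for v in codes[i]]
                fh.write(" ".join(row) + "\n")
    else:
        raise ValueError(f"unknown genotype dialect: {dialect!r}")


def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from TSV or PLINK .raw text.

    The TSV dialect round-trips bit-exactly with :func:`write_genotypes`.
    PLINK .raw columns carry a ``_<allele>`` suffix on SNP names, which is
    stripped.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        animal_col = df.columns[0]
        snp_ids = np.asarray(df.columns[1:], dtype=object)
        animals = df[animal_col].to_numpy(dtype=object)
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str})
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        missing_meta = [c for c in meta if c not in df.columns]
        if missing_meta:
            raise ValueError(f"not a PLINK .raw file, missing columns {missing_meta}")
        snp_cols = [c for c in df.columns if c not in meta]
        snp_ids = np.asarray(
            [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols], dtype=object
        )
        animals = df["IID"].to_numpy(dtype=object)
        values = df[snp_cols].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown genotype dialect: {dialect!r}")

    finite = values[~np.isnan(values)]
    bad = (finite < 0) | (finite > 2)
    if bad.any():
        # locate the first offender for the error message
        flat = np.where(~np.isnan(values) & ((values < 0) | (values > 2)))
        r, c = flat[0][0], flat[1][0]
        raise ValueError(
            f"invalid gene content {values[r, c]!r} at animal {animals[r]!r},"
            f" SNP {snp_ids[c]!r}"
        )
    return GenotypeMatrix(animals, snp_ids, values)


def write_snp_map(snp_map: pd.DataFrame, path) -> None:
    snp_map.to_csv(path, sep="\t", index=False)


def read_snp_map(path) -> pd.DataFrame:
    """Read a SNP map TSV with columns ``snp_id``, ``chrom``, ``pos`` (1-based bp)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    required = {"snp_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"SNP map must have columns {sorted(required)}")
    df["pos"] = df["pos"].astype(np.int64)
    return df


def validate_snp_map(snp_map: pd.DataFrame) -> None:
    """Check sortedness by (chrom, pos) and position uniqueness within chromosome."""
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError(
                f"SNP map not strictly increasing within chromosome {chrom!r}"
            )


def read_pedigree_frame(path) -> pd.DataFrame:
    """Read a 3-column pedigree CSV (animal, sire, dam; '0' = unknown parent)."""
    df = pd.read_csv(path, dtype=str).fillna("0")
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree must have columns {sorted(required)}")
    return df[["animal", "sire", "dam"]]


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal": str})
    if "animal" not in df.columns:
        raise ValueError("phenotype table must have an 'animal' column")
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def compute_maf(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP counted-allele frequency, MAF and call rate.

    Missing calls are excluded from the allele-count denominator.  SNPs with
    no observed calls get ``NaN`` frequencies; they are picked up by the
    call-rate filter downstream.
    """
    codes = geno.gene_content
    called = ~np.isnan(codes)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(codes, axis=0) / (2.0 * n_called)
    p = np.where(n_called == 0, np.nan, p)
    maf = np.minimum(p, 1.0 - p)
    call_rate = n_called / geno.n_animals
    return pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "p": p,
            "maf": maf,
            "call_rate": call_rate,
            "n_called": n_called,
        }
    )


def filter_snps(
    geno: GenotypeMatrix,
    snp_map: pd.DataFrame | None = None,
    maf_min: float = 0.01,
    callrate_min: float = 0.95,
):
    """Discard SNPs with MAF below ``maf_min`` or call rate below ``callrate_min``.

    Thresholds are strict lower bounds: a SNP exactly at the threshold is
    retained.  Returns ``(genotypes, snp_map, QcReport)``; ``snp_map`` is
    ``None`` when no map was supplied.
    """
    if not (0 <= maf_min <= 1) or not (0 <= callrate_min <= 1):
        raise ValueError("QC thresholds must lie in [0, 1]")
    if snp_map is not None and len(snp_map) != geno.n_snps:
        raise ValueError("genotypes and SNP map are not aligned")

    stats = compute_maf(geno)
    maf = stats["maf"].to_numpy()
    cr = stats["call_rate"].to_numpy()
    fail_maf = ~np.isnan(maf) & (maf < maf_min)
    fail_cr = ~fail_maf & ((cr < callrate_min) | np.isnan(maf))
    keep = ~fail_maf & ~fail_cr

    reason = np.where(fail_maf, "maf", np.where(fail_cr, "call_rate", "retained"))
    per_snp = stats.assign(status=reason)
    report = QcReport(
        n_input_snps=geno.n_snps,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_callrate=int(fail_cr.sum()),
        n_retained=int(keep.sum()),
        maf_min=maf_min,
        callrate_min=callrate_min,
        per_snp=per_snp,
    )
    out_map = snp_map.loc[keep].reset_index(drop=True) if snp_map is not None else None
    return geno.subset_snps(keep), out_map, report


def impute_missing(geno: GenotypeMatrix, method: str = "mean_dosage") -> GenotypeMatrix:
    """Fill missing calls with the mean dosage 2p of the observed calls.

    ``mean_dosage`` leaves a continuous dosage in [0, 2]; ``round_mean``
    rounds it to the nearest hard call in {0, 1, 2}.  This is a deliberately
    simple single-site fill; observed calls are never altered.
    """
    if method not in ("mean_dosage", "round_mean"):
        raise ValueError(f"unknown imputation method: {method!r}")
    codes = geno.gene_content
    if not np.isnan(codes).any():
        return geno
    stats = compute_maf(geno)
    p = stats["p"].to_numpy()
    if np.isnan(p).any():
        bad = geno.snp_ids[np.isnan(p)]
        raise ValueError(
            f"SNPs with no observed calls cannot be imputed, filter first: {list(bad)}"
        )
    fill = 2.0 * p
    if method == "round_mean":
        fill = np.clip(np.round(fill), 0, 2)
    out = codes.copy()
    rows, cols = np.where(np.isnan(out))
    out[rows, cols] = fill[cols]
    return GenotypeMatrix(geno.animal_ids.copy(), geno.snp_ids.copy(), out)


def log_transform(
    pheno: pd.DataFrame, columns: list[str] | None = None, suffix: str = "_log"
) -> pd.DataFrame:
    """Natural-log transform of strictly positive trait columns.

    Skewed concentration traits are analysed on the log scale; the transform
    is recorded in ``DataFrame.attrs['log_transform']``.
    """
    if columns is None:
        columns = [
            c
            for c in pheno.columns
            if c not in ("animal", "day") and pd.api.types.is_numeric_dtype(pheno[c])
            and not c.endswith(suffix)
        ]
    out = pheno.copy()
    for col in columns:
        vals = out[col].to_numpy(dtype=float)
        nonpos = vals <= 0
        if nonpos.any():
            offenders = out["animal"].to_numpy()[nonpos][:5]
            raise ValueError(
                f"non-positive {col!r} values for animals {list(offenders)}"
            )
        out[col + suffix] = np.log(vals)
    out.attrs["log_transform"] = {"base": "e", "columns": list(columns)}
    return out
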