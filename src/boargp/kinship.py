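"""Pedigree (A) and genomic (G) relationship matrices.

A is built with Henderson's tabular recursion from a topologically ordered
pedigree.  G follows VanRaden's first method: gene content centred by twice
the counted-allele frequency, scaled by 2*sum(p*(1-p)).  A small identity
blend is available to guarantee invertibility of G when markers are fewer
than animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .geno import GenotypeMatrix, compute_maf

__all__ = [
    "RelationshipMatrix",
    "KinshipInverse",
    "build_A",
    "build_G",
    "blend_and_invert",
    "write_relationship_matrix",
    "read_relationship_matrix",
]


@dataclass
class RelationshipMatrix:
    """Symmetric animals x animals relationship coefficients."""

    animal_ids: np.ndarray
    values: np.ndarray
    kind: str  # "pedigree_A" or "genomic_G"
    scale_denominator: float | None = None  # 2*sum(p*(1-p)) for genomic_G
    freqs: np.ndarray | None = None  # counted-allele frequencies used for Z

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = self.animal_ids.size
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n_animals(self) -> int:
        return self.animal_ids.size

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        missing = [a for a in ids if a not in lookup]
        if missing:
            raise KeyError(f"animals absent from relationship matrix: {missing[:10]}")
        return np.array([lookup[a] for a in ids], dtype=np.intp)


@dataclass
class KinshipInverse:
    """Inverse of an (optionally identity-blended) relationship matrix."""

    animal_ids: np.ndarray
    values: np.ndarray
    blend_weight: float
    kind: str


def build_A(ped) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``a_ii = 1 + 0.5 * a(sire, dam)`` and
    ``a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))`` for j earlier than i;
    an unknown parent contributes 0.  Requires parents to precede offspring.
    """
    sire_idx = np.asarray(ped.sire_idx, dtype=np.intp)
    dam_idx = np.asarray(ped.dam_idx, dtype=np.intp)
    n = sire_idx.size
    for i in range(n):
        if (sire_idx[i] >= i and sire_idx[i] != -1) or (
            dam_idx[i] >= i and dam_idx[i] != -1
        ):
            raise ValueError(
                f"pedigree not topologically ordered (or cyclic) at animal index {i}:"
                " parents must precede offspring"
            )
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        row = np.zeros(i)
        if s != -1:
            row += 0.5 * A[:i, s]
        if d != -1:
            row += 0.5 * A[:i, d]
        A[:i, i] = row
        A[i, :i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s != -1 and d != -1) else 0.0)
    return RelationshipMatrix(np.asarray(ped.animals, dtype=object), A, "pedigree_A")


def build_G(
    geno: GenotypeMatrix,
    freq_source: str = "observed",
    freqs: np.ndarray | None = None,
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix G = ZZ' / (2*sum(p*(1-p))).

    Z is the gene-content matrix column-centred by 2p, with p the frequency
    of the counted allele (computed from the analysed sample by default, or
    supplied for reproducibility across subsets).  Monomorphic SNPs make the
    centring degenerate and must be removed by QC first.
    """
    if geno.has_missing:
        raise ValueError("G requires complete genotypes; impute or filter first")
    if freq_source == "observed":
        p = compute_maf(geno)["p"].to_numpy()
    elif freq_source == "supplied":
        if freqs is None:
            raise ValueError("freq_source='supplied' requires freqs")
        p = np.asarray(freqs, dtype=float)
        if p.shape != (geno.n_snps,):
            raise ValueError("supplied freqs length does not match SNP count")
    else:
        raise ValueError(f"unknown freq_source: {freq_source!r}")
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        bad = geno.snp_ids[mono][:10]
        raise ValueError(
            f"monomorphic SNPs (p in {{0,1}}) — run the MAF filter first: {list(bad)}"
        )
    Z = geno.gene_content - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(
        geno.animal_ids.copy(), G, "genomic_G", scale_denominator=denom, freqs=p
    )


def center_gene_content(geno: GenotypeMatrix, freqs: np.ndarray) -> np.ndarray:
    """Z = M - 2p, the centred gene-content matrix underlying G."""
    if geno.has_missing:
        raise ValueError("centred gene content requires complete genotypes")
    return geno.gene_content - 2.0 * np.asarray(freqs, dtype=float)


def blend_and_invert(K: RelationshipMatrix, blend_weight: float = 0.01) -> KinshipInverse:
    """Invert ``(1 - w) * K + w * I``.

    ``w = 0`` requests an exact inverse (the default for pedigree A, which is
    positive definite by construction); rank-deficient G needs ``w > 0``.
    """
    if not (0.0 <= blend_weight < 1.0):
        raise ValueError("blend_weight must lie in [0, 1)")
    n = K.n_animals
    Kb = (1.0 - blend_weight) * K.values + blend_weight * np.eye(n)
    try:
        c, low = scipy.linalg.cho_factor(Kb)
        inv = scipy.linalg.cho_solve((c, low), np.eye(n))
        # Cholesky can "succeed" numerically on a singular matrix (e.g. G
        # centred by observed frequencies always has a zero eigenvalue);
        # verify the inverse actually inverts.
        residual = np.max(np.abs(Kb @ inv - np.eye(n)))
        if not np.isfinite(residual) or residual > 1e-6:
            raise np.linalg.LinAlgError(
                f"inverse residual {residual:.2e} — matrix numerically singular"
            )
    except np.linalg.LinAlgError as exc:
        if blend_weight == 0.0:
            raise np.linalg.LinAlgError(
                f"{K.kind} is singular at blend_weight=0; retry with a small"
                " identity blend (e.g. 0.01)"
            ) from exc
        raise
    inv = 0.5 * (inv + inv.T)
    return KinshipInverse(K.animal_ids.copy(), inv, blend_weight, K.kind)


def write_relationship_matrix(K: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(K.values, index=K.animal_ids, columns=K.animal_ids)
    with open(path, "w") as fh:
        fh.write(f"# kind={K.kind}")
        if K.scale_denominator is not None:
            fh.write(f" scale_denominator={float(K.scale_denominator)!r}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index_label="animal")


def read_relationship_matrix(path) -> RelationshipMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        meta = {}
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                meta[k] = v
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    kind = meta.get("kind", "pedigree_A")
    denom = float(meta["scale_denominator"]) if "scale_denominator" in meta else None
    return RelationshipMatrix(
        df.index.to_numpy(dtype=object), df.to_numpy(dtype=float), kind, denom
    )
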