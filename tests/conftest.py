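"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import boargp as bg

# QTL regions reported for the three boar-taint compounds (chromosome,
# region start/end in Mb, percentage of genetic variance explained), used to
# exercise the cross-trait interval-merging bookkeeping on published-scale
# coordinates.
QTL_WINDOWS = {
    "and": [
        ("1", 15.05, 15.44, 0.56),
        ("2", 1.23, 1.54, 0.58),
        ("2", 156.30, 156.65, 0.75),
        ("6", 135.01, 135.40, 0.90),
        ("6", 140.66, 141.06, 0.53),
        ("7", 18.15, 18.54, 0.62),
        ("8", 128.63, 128.99, 0.58),
        ("9", 27.88, 28.27, 0.73),
    ],
    "ind": [
        ("1", 29.76, 30.15, 0.52),
        ("2", 140.25, 140.64, 0.56),
        ("4", 15.44, 15.74, 0.58),
        ("4", 141.08, 141.46, 0.86),
        ("6", 134.85, 135.24, 0.78),
        ("6", 140.95, 141.31, 0.63),
        ("8", 17.93, 18.32, 0.90),
        ("14", 3.77, 4.13, 0.67),
    ],
    "ska": [
        ("1", 30.00, 30.38, 0.58),
        ("4", 15.44, 15.74, 0.50),
        ("13", 9.55, 9.94, 0.54),
        ("13", 204.99, 205.38, 0.89),
        ("15", 137.53, 137.93, 0.64),
        ("18", 0.76, 1.12, 0.61),
    ],
}


def qtl_window_frames() -> dict:
    """Per-trait window tables (bp coordinates) from the published regions."""
    out = {}
    for trait, rows in QTL_WINDOWS.items():
        out[trait] = pd.DataFrame(
            [
                {
                    "chrom": c,
                    "start_bp": int(round(s * 1e6)),
                    "end_bp": int(round(e * 1e6)),
                    "pct_variance": v,
                }
                for c, s, e, v in rows
            ]
        )
    return out


def small_config(**kw) -> bg.SimConfig:
    """A fast config: ~200 animals, 500 SNPs on 5 chromosomes."""
    base = dict(
        n_founders=40,
        n_generations=2,
        offspring_per_mating=4,
        n_chromosomes=5,
        n_snps=500,
        chrom_length_bp=30_000_000,
        maf_range=(0.1, 0.5),
        n_qtl=50,
        h2_target=0.30,
        n_day_levels=10,
        day_variance_ratio=0.10,
        seed=11,
    )
    base.update(kw)
    return bg.SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """Simulated, QC'd small dataset shared by read-only tests."""
    cfg = small_config()
    ped, geno, snp_map, pheno, truth = bg.simulate_dataset(cfg)
    geno, snp_map, report = bg.filter_snps(geno, snp_map)
    return {
        "cfg": cfg,
        "ped": ped,
        "geno": geno,
        "map": snp_map,
        "pheno": pheno,
        "truth": truth,
        "qc": report,
    }


@pytest.fixture(scope="session")
def small_blup(small_dataset):
    """Full-data PBLUP and GBLUP fits on the small dataset."""
    d = small_dataset
    spec = bg.ModelSpec(trait="and_log")
    A = bg.build_A(d["ped"])
    G = bg.build_G(d["geno"])
    s2a, s2d, s2e = d["truth"].true_variance_components
    vc = bg.VarianceComponents(s2a, s2d, s2e)
    solA = bg.solve_blup(d["pheno"], spec, A, vc)
    solG = bg.solve_blup(d["pheno"], spec, G, vc)
    return {"spec": spec, "A": A, "G": G, "vc": vc, "solA": solA, "solG": solG}


@pytest.fixture(scope="session")
def fullrank_gblup():
    """200 x ~500 dataset with a full-rank (supplied-frequency) G and its solve.

    Observed-frequency centring makes G exactly singular, so the exact
    GBLUP/SNP-BLUP identities are checked on a G built from slightly shrunk
    frequencies, which is full rank and needs no blending.
    """
    cfg = small_config(seed=5)
    ped, geno, snp_map, pheno, truth = bg.simulate_dataset(cfg)
    geno, snp_map, _ = bg.filter_snps(geno, snp_map)
    p_obs = bg.compute_maf(geno)["p"].to_numpy()
    p = 0.9 * p_obs + 0.05
    G = bg.build_G(geno, freq_source="supplied", freqs=p)
    spec = bg.ModelSpec(trait="and_log")
    s2a, s2d, s2e = truth.true_variance_components
    vc = bg.VarianceComponents(s2a, s2d, s2e)
    sol = bg.solve_blup(pheno, spec, G, vc, blend_weight=0.0)
    Z = geno.gene_content - 2.0 * p
    return {
        "geno": geno,
        "map": snp_map,
        "pheno": pheno,
        "G": G,
        "Z": Z,
        "spec": spec,
        "vc": vc,
        "sol": sol,
    }


def gametic_gene_drop(ped, n_reps: int, seed: int) -> np.ndarray:
    """Monte-Carlo estimate of A by dropping gametic values down the pedigree.

    Each founder gamete carries an independent N(0, 1/2) value; a meiosis
    passes one of the parent's two gametic values chosen at random.  Animal
    values are the sum of their two gametes, so Cov(u_i, u_j) = A_ij exactly
    in expectation (including inbreeding).  Independent of the tabular
    recursion being tested.
    """
    rng = np.random.default_rng(seed)
    n = ped.n_animals
    pat = np.empty((n, n_reps))
    mat = np.empty((n, n_reps))
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s == -1:
            pat[i] = rng.normal(0.0, np.sqrt(0.5), n_reps)
        else:
            pick = rng.random(n_reps) < 0.5
            pat[i] = np.where(pick, pat[s], mat[s])
        if d == -1:
            mat[i] = rng.normal(0.0, np.sqrt(0.5), n_reps)
        else:
            pick = rng.random(n_reps) < 0.5
            mat[i] = np.where(pick, pat[d], mat[d])
    u = pat + mat
    return (u @ u.T) / n_reps
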