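"""Synthetic pedigree, genotype and phenotype generation.

The generator emulates the data structure of a purebred pig sire line
phenotyped for boar-taint compound concentrations: a multi-generation
pedigree, SNP-chip genotypes gene-dropped through that pedigree with
recombination (so that genomic and pedigree relationships agree in
expectation), and log-normal phenotypes composed of a mean, a random
day-of-analysis effect, a true breeding value (TBV) built from QTL, and a
residual.

Default parameter values follow the emulated study design: ~1050 animals,
29,844 SNPs on 18 autosomes, a 91-level day effect, and an androstenone-like
log-scale phenotype with mean 6.77, SD 0.76 and heritability 0.30.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geno import GenotypeMatrix, write_genotypes, write_phenotypes, write_snp_map

__all__ = [
    "SimConfig",
    "Pedigree",
    "TrueValues",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "inject_missing",
    "write_dataset",
]

# fixed spawn keys for the independent random streams derived from the seed
_STREAM_PEDIGREE = 0
_STREAM_GENOTYPES = 1
_STREAM_PHENOTYPES = 2
_STREAM_MISSING = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))
    )


@dataclass
class SimConfig:
    """Parameters of the synthetic study population.

    ``h2_target`` is the heritability on the day-adjusted scale,
    sigma2_a / (sigma2_a + sigma2_e); ``day_variance_ratio`` is the share of
    total phenotypic variance taken by the random day-of-analysis effect.
    Recombination follows a Haldane map at ``recomb_rate_per_bp`` (default
    1e-8, i.e. 1 cM/Mb, no interference).
    """

    n_founders: int = 50
    n_generations: int = 4
    offspring_per_mating: int = 10
    n_chromosomes: int = 18
    n_snps: int = 29844
    chrom_length_bp: int = 90_000_000
    maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 300
    h2_target: float = 0.30
    n_day_levels: int = 91
    day_variance_ratio: float = 0.10
    phenotype_mean_log: float = 6.77
    phenotype_sd_log: float = 0.76
    recomb_rate_per_bp: float = 1e-8
    qtl_effect_dist: str = "normal"  # or "equal": |effect| identical, random sign
    trait: str = "and"
    seed: int = 42

    def validate(self) -> None:
        if not (0.0 < self.h2_target < 1.0):
            raise ValueError("h2_target must lie strictly in (0, 1)")
        if self.day_variance_ratio < 0:
            raise ValueError("day_variance_ratio must be non-negative")
        if self.h2_target + self.day_variance_ratio >= 1.0:
            raise ValueError("h2_target + day_variance_ratio must be < 1")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.n_day_levels < 1:
            raise ValueError("n_day_levels must be >= 1")
        if self.qtl_effect_dist not in ("normal", "equal"):
            raise ValueError("qtl_effect_dist must be 'normal' or 'equal'")

    def variance_components(self) -> tuple[float, float, float]:
        """(sigma2_a, sigma2_day, sigma2_e) implied by the config."""
        total = self.phenotype_sd_log ** 2
        s2_day = self.day_variance_ratio * total
        s2_ae = total - s2_day
        s2_a = self.h2_target * s2_ae
        s2_e = s2_ae - s2_a
        return s2_a, s2_day, s2_e


@dataclass
class Pedigree:
    """Topologically ordered pedigree: parents precede offspring.

    ``sire_idx``/``dam_idx`` index into ``animals``; -1 marks an unknown
    parent (founders).
    """

    animals: np.ndarray
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    sex: np.ndarray | None = None
    generation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.animals = np.asarray(self.animals, dtype=object)
        self.sire_idx = np.asarray(self.sire_idx, dtype=np.intp)
        self.dam_idx = np.asarray(self.dam_idx, dtype=np.intp)
        if pd.unique(self.animals).size != self.animals.size:
            raise ValueError("duplicated animal ids in pedigree")
        for i in range(self.n_animals):
            if self.sire_idx[i] >= i or self.dam_idx[i] >= i:
                raise ValueError(
                    "pedigree not topologically ordered: parents must precede"
                    f" offspring (animal index {i})"
                )

    @property
    def n_animals(self) -> int:
        return self.animals.size

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire_idx == -1) & (self.dam_idx == -1)

    def to_frame(self) -> pd.DataFrame:
        def name(idx: int) -> str:
            return "0" if idx == -1 else str(self.animals[idx])

        return pd.DataFrame(
            {
                "animal": [str(a) for a in self.animals],
                "sire": [name(i) for i in self.sire_idx],
                "dam": [name(i) for i in self.dam_idx],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        animals = df["animal"].astype(str).to_numpy(dtype=object)
        lookup = {a: i for i, a in enumerate(animals)}

        def idx(parent: str) -> int:
            if parent in ("0", "", "nan", "NA"):
                return -1
            if parent not in lookup:
                raise ValueError(f"parent {parent!r} has no own pedigree record")
            return lookup[parent]

        sire = np.array([idx(s) for s in df["sire"].astype(str)], dtype=np.intp)
        dam = np.array([idx(d) for d in df["dam"].astype(str)], dtype=np.intp)
        return cls(animals, sire, dam)


@dataclass
class TrueValues:
    """Simulation ground truth for recovery tests."""

    true_breeding_values: np.ndarray
    qtl_positions: np.ndarray
    qtl_effects: np.ndarray
    true_variance_components: tuple
    day_effects: np.ndarray = field(default=None)


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Discrete-generation pedigree with random mating within generation.

    Founders alternate sex so both sexes always exist; each later generation
    consists of ``n_founders // 2`` matings of sires/dams sampled (with
    replacement) from the previous generation, each producing
    ``offspring_per_mating`` offspring.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_PEDIGREE)
    animals: list[str] = []
    sire_idx: list[int] = []
    dam_idx: list[int] = []
    sex: list[str] = []
    gen: list[int] = []

    for i in range(config.n_founders):
        animals.append(f"A{len(animals) + 1:05d}")
        sire_idx.append(-1)
        dam_idx.append(-1)
        sex.append("M" if i % 2 == 0 else "F")
        gen.append(0)

    prev = list(range(config.n_founders))
    n_matings = config.n_founders // 2
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if sex[i] == "M"]
        females = [i for i in prev if sex[i] == "F"]
        if not males or not females:
            raise ValueError(f"generation {g - 1} lacks one sex; cannot mate")
        sires = rng.choice(males, size=n_matings, replace=True)
        dams = rng.choice(females, size=n_matings, replace=True)
        current: list[int] = []
        for s, d in zip(sires, dams):
            for _ in range(config.offspring_per_mating):
                idx = len(animals)
                animals.append(f"A{idx + 1:05d}")
                sire_idx.append(int(s))
                dam_idx.append(int(d))
                sex.append("M" if rng.random() < 0.5 else "F")
                gen.append(g)
                current.append(idx)
        prev = current

    return Pedigree(
        np.array(animals, dtype=object),
        np.array(sire_idx, dtype=np.intp),
        np.array(dam_idx, dtype=np.intp),
        sex=np.array(sex, dtype=object),
        generation=np.array(gen, dtype=np.intp),
    )


def _make_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    counts = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    counts[: config.n_snps % config.n_chromosomes] += 1
    rows = []
    snp_no = 0
    for c in range(config.n_chromosomes):
        m_c = int(counts[c])
        pos: np.ndarray = np.unique(
            rng.integers(1, config.chrom_length_bp + 1, size=m_c)
        )
        while pos.size < m_c:  # top up collisions (rare at chip density)
            extra = rng.integers(1, config.chrom_length_bp + 1, size=m_c - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(pos[:m_c])
        for p in pos:
            snp_no += 1
            rows.append((f"SNP{snp_no:06d}", str(c + 1), int(p)))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


def _gamete(
    pat: np.ndarray,
    mat: np.ndarray,
    chrom_slices: list,
    chrom_pos: list,
    chrom_len: int,
    rate: float,
    rng: np.random.Generator,
    out: np.ndarray,
) -> None:
    """One meiosis: fill ``out`` with a recombined gamete of a parent."""
    for sl, pos in zip(chrom_slices, chrom_pos):
        start = rng.integers(2)
        if rate > 0:
            n_cx = rng.poisson(rate * chrom_len)
        else:
            n_cx = 0
        if n_cx == 0:
            out[sl] = pat[sl] if start == 0 else mat[sl]
            continue
        cx = np.sort(rng.integers(1, chrom_len + 1, size=n_cx))
        phase = (start + np.searchsorted(cx, pos, side="right")) % 2
        seg = np.where(phase == 0, pat[sl], mat[sl])
        out[sl] = seg


def simulate_genotypes(pedigree: Pedigree, config: SimConfig):
    """Gene-drop genotypes through the pedigree with Haldane recombination.

    Founder haplotypes are drawn site-wise from Bernoulli(p) with p uniform
    in ``maf_range`` (counted allele chosen at random, so the counted-allele
    frequency is p or 1-p); non-founders inherit one recombined gamete from
    each parent.  Returns ``(GenotypeMatrix, snp_map)``.
    """
    config.validate()
    if pedigree.n_animals == 0:
        raise ValueError("empty pedigree")
    rng = _rng(config.seed, _STREAM_GENOTYPES)
    snp_map = _make_map(config, rng)

    m = len(snp_map)
    u = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    flip = rng.random(m) < 0.5
    p = np.where(flip, 1.0 - u, u)

    chrom_slices = []
    chrom_pos = []
    offset = 0
    for _, grp in snp_map.groupby("chrom", sort=False):
        k = len(grp)
        chrom_slices.append(slice(offset, offset + k))
        chrom_pos.append(grp["pos"].to_numpy())
        offset += k

    n = pedigree.n_animals
    hap_pat = np.zeros((n, m), dtype=np.int8)
    hap_mat = np.zeros((n, m), dtype=np.int8)
    rate = config.recomb_rate_per_bp
    for i in range(n):
        s, d = pedigree.sire_idx[i], pedigree.dam_idx[i]
        if s == -1 and d == -1:
            hap_pat[i] = rng.random(m) < p
            hap_mat[i] = rng.random(m) < p
        else:
            # unknown single parents draw a population gamete
            if s == -1:
                hap_pat[i] = rng.random(m) < p
            else:
                _gamete(
                    hap_pat[s], hap_mat[s], chrom_slices, chrom_pos,
                    config.chrom_length_bp, rate, rng, hap_pat[i],
                )
            if d == -1:
                hap_mat[i] = rng.random(m) < p
            else:
                _gamete(
                    hap_pat[d], hap_mat[d], chrom_slices, chrom_pos,
                    config.chrom_length_bp, rate, rng, hap_mat[i],
                )

    gene_content = (hap_pat + hap_mat).astype(float)
    geno = GenotypeMatrix(pedigree.animals.copy(), snp_map["snp_id"].to_numpy(dtype=object), gene_content)
    return geno, snp_map


def simulate_phenotypes(geno: GenotypeMatrix, config: SimConfig):
    """Log-scale phenotypes y = mu + day effect + TBV + residual.

    The TBV is a sum over ``n_qtl`` causal SNPs of effect * (gene content -
    2p), with effects drawn normal and rescaled post hoc so the realized
    var(TBV) equals sigma2_a exactly.  Animals are assigned to analysis days
    in contiguous blocks (batched lab analysis); day effects are i.i.d.
    normal.  The raw-scale phenotype is exp(y).  Returns
    ``(PhenotypeTable, TrueValues)``.
    """
    config.validate()
    if geno.has_missing:
        raise ValueError("phenotype simulation requires complete genotypes")
    rng = _rng(config.seed, _STREAM_PHENOTYPES)
    n, m = geno.n_animals, geno.n_snps
    s2_a, s2_day, s2_e = config.variance_components()

    if config.qtl_effect_dist == "equal":
        # planted QTL are drawn among common variants (realized MAF >= 0.2):
        # a rare planted allele is weakly tagged by markers and would not
        # carry a dependable variance share
        freq = geno.gene_content.mean(axis=0) / 2.0
        common = np.where(np.minimum(freq, 1 - freq) >= 0.2)[0]
        if common.size < config.n_qtl:
            raise ValueError("not enough common SNPs to plant the QTL")
        qtl_idx = np.sort(rng.choice(common, size=config.n_qtl, replace=False))
    else:
        qtl_idx = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    if config.qtl_effect_dist == "equal":
        # planted major QTL: effects scaled by the realized dosage SD so each
        # QTL contributes an equal share of the genetic variance regardless
        # of drift in its allele frequency; random sign
        sd = geno.gene_content[:, qtl_idx].std(axis=0)
        if np.any(sd <= 0):
            raise ValueError("monomorphic QTL cannot carry an equal share")
        effects = rng.choice([-1.0, 1.0], size=config.n_qtl) / sd
    else:
        effects = rng.standard_normal(config.n_qtl)
    X = geno.gene_content[:, qtl_idx]
    p_qtl = X.mean(axis=0) / 2.0
    tbv_raw = (X - 2.0 * p_qtl) @ effects
    v = tbv_raw.var()
    if v <= 0:
        raise ValueError("degenerate QTL set: zero TBV variance (monomorphic QTL?)")
    scale = np.sqrt(s2_a / v)
    tbv = tbv_raw * scale
    effects = effects * scale

    blocks = np.array_split(np.arange(n), config.n_day_levels)
    day = np.empty(n, dtype=np.intp)
    for lvl, idx in enumerate(blocks):
        day[idx] = lvl + 1
    day_effects = rng.normal(0.0, np.sqrt(s2_day), size=config.n_day_levels)
    resid = rng.normal(0.0, np.sqrt(s2_e), size=n)

    y_log = config.phenotype_mean_log + day_effects[day - 1] + tbv + resid
    pheno = pd.DataFrame(
        {
            "animal": [str(a) for a in geno.animal_ids],
            "day": day,
            config.trait: np.exp(y_log),
            f"{config.trait}_log": y_log,
        }
    )
    pheno.attrs["log_transform"] = {"base": "e", "columns": [config.trait]}
    truth = TrueValues(
        true_breeding_values=tbv,
        qtl_positions=qtl_idx,
        qtl_effects=effects,
        true_variance_components=(s2_a, s2_day, s2_e),
        day_effects=day_effects,
    )
    return pheno, truth


def simulate_dataset(config: SimConfig):
    """Pedigree, genotypes, map, phenotypes and ground truth in one call."""
    ped = simulate_pedigree(config)
    geno, snp_map = simulate_genotypes(ped, config)
    pheno, truth = simulate_phenotypes(geno, config)
    return ped, geno, snp_map, pheno, truth


def inject_missing(geno: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set a random fraction of calls to missing (QC-filter testing aid)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("missing rate must lie in [0, 1)")
    rng = _rng(seed, _STREAM_MISSING)
    out = geno.gene_content.copy()
    mask = rng.random(out.shape) < rate
    out[mask] = np.nan
    return GenotypeMatrix(geno.animal_ids.copy(), geno.snp_ids.copy(), out)


def write_dataset(outdir, ped: Pedigree, geno: GenotypeMatrix, snp_map, pheno) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped.to_frame().to_csv(outdir / "pedigree.csv", index=False)
    write_phenotypes(pheno, outdir / "phenotypes.csv")
    write_genotypes(geno, outdir / "genotypes.tsv", dialect="tsv")
    write_genotypes(geno, outdir / "genotypes.raw", dialect="plink_raw")
    write_snp_map(snp_map, outdir / "snp_map.tsv")
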