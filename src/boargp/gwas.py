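"""GBLUP-GWAS: SNP effects back-solved from GEBV, window variance, QTL.

SNP allele-substitution effects are recovered from genomic breeding values
by the linear transformation g_hat = Z' G^-1 u_hat / (2*sum(p*(1-p))), their
sampling standard deviations from the prediction-error (co)variances of the
GEBV, and p-values from a two-sided normal test of g_hat / sd(g_hat).  The
genome is then tiled into consecutive 0.4 Mb windows of adjacent SNPs, each
window's share of the genetic variance is the variance across animals of its
partial breeding value Z_w g_w, and windows at or above a percentage
threshold become putative QTL regions.  Candidate genes are looked up by
interval overlap with a local annotation within a flank of the lead SNP.

Coordinate conventions: SNP positions 1-based bp; windows half-open
[start, start + window_bp); QTL region boundaries closed, taken from the
constituent SNP positions; the gene flank around the lead SNP is a closed
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .geno import GenotypeMatrix
from .kinship import RelationshipMatrix, blend_and_invert
from .mixedmodel import BlupSolution

__all__ = [
    "WindowTable",
    "QtlRegion",
    "BonferroniThreshold",
    "backsolve_snp_effects",
    "snp_pvalues",
    "bonferroni_threshold",
    "make_windows",
    "window_variance",
    "select_qtl",
    "expected_window_contribution",
    "candidate_genes",
    "read_gene_annotation",
    "export_manhattan",
]


@dataclass
class BonferroniThreshold:
    m: int
    alpha: float
    p_threshold: float
    neg_log10: float

    @property
    def neg_log10_display(self) -> float:
        return round(self.neg_log10, 2)


@dataclass
class WindowTable:
    """Consecutive SNP windows tiling each chromosome.

    ``table`` has one row per non-empty window (window_id, chrom, start_bp,
    end_bp half-open, n_snps, and pct_variance once completed);
    ``assignment`` maps each SNP (map order) to its row in ``table``.
    """

    table: pd.DataFrame
    assignment: np.ndarray
    window_bp: int


@dataclass
class QtlRegion:
    """A merged genomic region whose windows pass the variance threshold."""

    traits: tuple
    chromosome: str
    start_bp: int
    end_bp: int
    members: pd.DataFrame = field(repr=False)  # one row per (trait, window)

    @property
    def shared_with(self) -> dict:
        return {
            t: tuple(sorted(set(self.traits) - {t})) for t in self.traits
        }


def _check_alignment(solution: BlupSolution, geno: GenotypeMatrix) -> None:
    if solution.animal_ids.size != geno.n_animals or np.any(
        solution.animal_ids != geno.animal_ids
    ):
        missing = sorted(
            set(map(str, solution.animal_ids)) ^ set(map(str, geno.animal_ids))
        )[:10]
        raise ValueError(
            f"animal sets of GEBV solution and genotypes differ (e.g. {missing})"
        )


def _blended_G(G: RelationshipMatrix, w: float) -> np.ndarray:
    return (1.0 - w) * G.values + w * np.eye(G.n_animals)


def backsolve_snp_effects(
    solution: BlupSolution, geno: GenotypeMatrix, G: RelationshipMatrix
) -> pd.DataFrame:
    """SNP effects g_hat = Z' G^-1 u_hat / (2*sum(p*(1-p))).

    Z is centred with the same allele frequencies used to build G, and G^-1
    is the blended inverse when the BLUP solve used blending, so that
    Z g_hat reconstructs u_hat exactly in the unblended full-rank case.
    """
    _check_alignment(solution, geno)
    if G.scale_denominator is None or G.freqs is None:
        raise ValueError("G must be a genomic matrix with recorded frequencies")
    Ginv = blend_and_invert(G, solution.blend_weight).values
    Z = geno.gene_content - 2.0 * G.freqs
    g_hat = (Z.T @ (Ginv @ solution.u_hat)) / G.scale_denominator
    return pd.DataFrame({"snp_id": geno.snp_ids, "g_hat": g_hat})


def snp_pvalues(
    effects: pd.DataFrame,
    solution: BlupSolution,
    geno: GenotypeMatrix,
    G: RelationshipMatrix,
) -> pd.DataFrame:
    """Complete the SNP-effect table with sd(g_hat), p-values and -log10 p.

    Var(u_hat) is taken as sigma2_a * G - PEV (the prediction-error
    covariance block of the inverse mixed-model equations), propagated
    through the back-solving transform:
    Var(g_hat) = k Z'G^-1 Var(u_hat) G^-1 Z k with k = 1/(2*sum(p*(1-p))).
    p_i = 2 * (1 - Phi(|g_i| / sd(g_i))).
    """
    _check_alignment(solution, geno)
    if solution.vc is None:
        raise ValueError("solution must carry its variance components")
    w = solution.blend_weight
    Gb = _blended_G(G, w)
    Ginv = blend_and_invert(G, w).values
    Z = geno.gene_content - 2.0 * G.freqs
    var_u = solution.vc.sigma2_a * Gb - solution.pev_matrix
    B = Ginv @ Z
    k = 1.0 / G.scale_denominator
    var_g = k**2 * np.einsum("ij,ij->j", B, var_u @ B)
    if np.any(var_g <= 0):
        bad = geno.snp_ids[var_g <= 0][:10]
        raise ValueError(
            f"non-positive SNP-effect variance (numerical breakdown): {list(bad)}"
        )
    sd = np.sqrt(var_g)
    g = effects["g_hat"].to_numpy()
    z = np.abs(g) / sd
    p = 2.0 * scipy.stats.norm.sf(z)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = effects.copy()
    out["sd_g_hat"] = sd
    out["p_value"] = p
    out["neg_log10_p"] = -np.log10(p)
    return out


def bonferroni_threshold(m: int, alpha: float = 0.05) -> BonferroniThreshold:
    """Genome-wide significance threshold alpha / m after Bonferroni correction."""
    if m < 1:
        raise ValueError("m must be at least 1")
    thr = alpha / m
    return BonferroniThreshold(m, alpha, thr, float(-np.log10(thr)))


def make_windows(
    snp_map: pd.DataFrame, window_bp: int = 400_000, anchor: str = "first_snp"
) -> WindowTable:
    """Tile each chromosome into consecutive non-overlapping windows.

    Windows are anchored at the first SNP of the chromosome (or at bp 0 with
    ``anchor='zero'``), are half-open [start, start + window_bp), and empty
    windows are dropped.  Every SNP lands in exactly one window.
    """
    if anchor not in ("first_snp", "zero"):
        raise ValueError(f"unknown anchor: {anchor!r}")
    rows = []
    assignment = np.empty(len(snp_map), dtype=np.intp)
    row_no = 0
    offset = 0
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"SNP map unsorted within chromosome {chrom!r}")
        base = int(pos[0]) if anchor == "first_snp" else 0
        widx = (pos - base) // window_bp
        for wv in np.unique(widx):
            in_w = widx == wv
            start = base + int(wv) * window_bp
            rows.append(
                {
                    "window_id": f"{chrom}:{start}",
                    "chrom": str(chrom),
                    "start_bp": start,
                    "end_bp": start + window_bp,
                    "n_snps": int(in_w.sum()),
                    "first_snp_bp": int(pos[in_w][0]),
                    "last_snp_bp": int(pos[in_w][-1]),
                }
            )
            assignment[offset + np.where(in_w)[0]] = row_no
            row_no += 1
        offset += len(grp)
    return WindowTable(pd.DataFrame(rows), assignment, window_bp)


def window_variance(
    geno: GenotypeMatrix,
    effects: pd.DataFrame,
    windows: WindowTable,
    solution: BlupSolution,
    G: RelationshipMatrix,
    denominator: str = "gebv_var",
    snp_map: pd.DataFrame | None = None,
) -> WindowTable:
    """Percentage of genetic variance explained by each SNP window.

    The partial breeding value of window w is u_w = Z_w g_w across animals;
    its variance is expressed as a percentage of the variance of the total
    GEBV (default) or of sigma2_a (``denominator='sigma2_a'``).  The lead
    SNP of a window is the one with the largest |g_hat|.
    """
    if len(effects) != geno.n_snps:
        raise ValueError("effects and genotypes are not aligned")
    g = effects["g_hat"].to_numpy()
    Z = geno.gene_content - 2.0 * G.freqs
    if denominator == "gebv_var":
        denom = solution.u_hat.var()
    elif denominator == "sigma2_a":
        if solution.vc is None:
            raise ValueError("sigma2_a denominator needs variance components")
        denom = solution.vc.sigma2_a
    else:
        raise ValueError(f"unknown denominator: {denominator!r}")
    if denom <= 0:
        raise ValueError("zero genetic variance denominator")

    table = windows.table.copy()
    pct = np.zeros(len(table))
    lead_snp = np.empty(len(table), dtype=object)
    lead_pos = np.zeros(len(table), dtype=np.int64)
    for r in range(len(table)):
        cols = np.where(windows.assignment == r)[0]
        u_w = Z[:, cols] @ g[cols]
        pct[r] = 100.0 * u_w.var() / denom
        lead = cols[np.argmax(np.abs(g[cols]))]
        lead_snp[r] = geno.snp_ids[lead]
        lead_pos[r] = lead
    table["pct_variance"] = pct
    table["lead_snp"] = lead_snp
    table["lead_snp_index"] = lead_pos
    if snp_map is not None:
        table["lead_snp_bp"] = snp_map["pos"].to_numpy()[lead_pos]
    return WindowTable(table, windows.assignment.copy(), windows.window_bp)


def expected_window_contribution(n_windows: int, threshold_pct: float = 0.5):
    """Expected % of genetic variance per window (100/N) and the threshold multiple.

    Under equal contribution of all N windows each explains 100/N percent;
    the returned multiple says how many times that expectation the selection
    threshold represents.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be at least 1")
    expected = 100.0 / n_windows
    return expected, threshold_pct / expected


def select_qtl(
    windows_per_trait: dict, threshold_pct: float = 0.5
) -> list[QtlRegion]:
    """Select windows explaining >= threshold_pct of the genetic variance.

    ``windows_per_trait`` maps trait name to either a completed
    :class:`WindowTable` or a plain DataFrame with columns chrom, start_bp,
    end_bp, pct_variance (and optionally lead_snp / lead-snp position and
    n_snps).  Selected windows from different traits on the same chromosome
    whose intervals overlap are merged into a single shared region.  Region
    boundaries are taken from constituent SNP positions when available.
    """
    selected = []
    for trait, wt in windows_per_trait.items():
        df = wt.table if isinstance(wt, WindowTable) else wt
        hits = df.loc[df["pct_variance"] >= threshold_pct].copy()
        hits["trait"] = trait
        # prefer SNP-derived boundaries when present
        if "first_snp_bp" in hits.columns:
            hits["region_start"] = hits["first_snp_bp"]
            hits["region_end"] = hits["last_snp_bp"]
        else:
            hits["region_start"] = hits["start_bp"]
            hits["region_end"] = hits["end_bp"]
        selected.append(hits)
    if not selected:
        return []
    allw = pd.concat(selected, ignore_index=True)
    if len(allw) == 0:
        return []

    regions: list[QtlRegion] = []
    for chrom, grp in allw.groupby("chrom", sort=False):
        grp = grp.sort_values("region_start")
        current: list = []
        cur_end = -np.inf
        for _, row in grp.iterrows():
            if current and row["region_start"] > cur_end:
                regions.append(_finish_region(str(chrom), current))
                current = []
                cur_end = -np.inf
            current.append(row)
            cur_end = max(cur_end, row["region_end"])
        if current:
            regions.append(_finish_region(str(chrom), current))
    return regions


def _finish_region(chrom: str, rows: list) -> QtlRegion:
    members = pd.DataFrame(rows).reset_index(drop=True)
    traits = tuple(sorted(pd.unique(members["trait"])))
    return QtlRegion(
        traits=traits,
        chromosome=chrom,
        start_bp=int(members["region_start"].min()),
        end_bp=int(members["region_end"].max()),
        members=members,
    )


def read_gene_annotation(path, dialect: str) -> pd.DataFrame:
    """Read gene annotation as BED (0-based half-open) or TSV (1-based inclusive).

    Returns a DataFrame with 1-based inclusive ``start_bp``/``end_bp``.
    """
    path = Path(path)
    if dialect == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        if df.shape[1] < 4:
            raise ValueError("BED annotation needs chrom, start, end, name columns")
        out = pd.DataFrame(
            {
                "gene_id": df.iloc[:, 3].astype(str),
                "symbol": df.iloc[:, 3].astype(str),
                "chrom": df.iloc[:, 0].astype(str),
                "start_bp": df.iloc[:, 1].astype(np.int64) + 1,
                "end_bp": df.iloc[:, 2].astype(np.int64),
            }
        )
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
        required = {"gene_id", "chrom", "start_bp", "end_bp"}
        if not required.issubset(df.columns):
            raise ValueError(f"gene TSV must have columns {sorted(required)}")
        out = df.copy()
        if "symbol" not in out.columns:
            out["symbol"] = out["gene_id"]
    else:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    if (out["start_bp"] > out["end_bp"]).any():
        raise ValueError("gene with start > end in annotation")
    return out


def candidate_genes(
    regions: list[QtlRegion],
    annotation: pd.DataFrame,
    flank_bp: int = 200_000,
    snp_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Genes within ``flank_bp`` (closed interval) of each region's lead SNP.

    For merged multi-trait regions each member window contributes its own
    lead SNP; hits are deduplicated per region and ordered by distance to
    the nearest lead SNP.  Lead-SNP bp positions are taken from the member
    table's ``lead_snp_bp`` column or looked up in ``snp_map``.
    """
    if len(annotation) == 0:
        return pd.DataFrame(
            columns=["region", "chrom", "gene_id", "symbol", "start_bp", "end_bp",
                     "lead_snp_bp", "distance_bp", "traits"]
        )
    ann_chroms = set(annotation["chrom"].astype(str))
    unmatched = sorted(
        {r.chromosome for r in regions} - ann_chroms
    )
    if unmatched:
        raise ValueError(
            f"chromosome labels absent from annotation: {unmatched}"
        )
    pos_lookup = None
    if snp_map is not None:
        pos_lookup = dict(zip(snp_map["snp_id"].astype(str), snp_map["pos"]))

    rows = []
    for r in regions:
        region_name = f"{r.chromosome}:{r.start_bp}-{r.end_bp}"
        leads = []
        for _, m in r.members.iterrows():
            if "lead_snp_bp" in r.members.columns and pd.notna(m.get("lead_snp_bp")):
                leads.append(int(m["lead_snp_bp"]))
            elif pos_lookup is not None and str(m.get("lead_snp")) in pos_lookup:
                leads.append(int(pos_lookup[str(m["lead_snp"])]))
        if not leads:
            raise ValueError(
                f"region {region_name} lacks a lead-SNP position; supply snp_map"
            )
        ann_c = annotation.loc[annotation["chrom"].astype(str) == r.chromosome]
        best: dict = {}
        for lead in leads:
            lo, hi = lead - flank_bp, lead + flank_bp
            hit = ann_c.loc[(ann_c["start_bp"] <= hi) & (ann_c["end_bp"] >= lo)]
            for _, gr in hit.iterrows():
                if gr["start_bp"] <= lead <= gr["end_bp"]:
                    dist = 0
                else:
                    dist = int(
                        min(abs(gr["start_bp"] - lead), abs(gr["end_bp"] - lead))
                    )
                key = gr["gene_id"]
                if key not in best or dist < best[key][0]:
                    best[key] = (dist, lead, gr)
        for gene_id, (dist, lead, gr) in sorted(
            best.items(), key=lambda kv: kv[1][0]
        ):
            rows.append(
                {
                    "region": region_name,
                    "chrom": r.chromosome,
                    "gene_id": gene_id,
                    "symbol": gr["symbol"],
                    "start_bp": int(gr["start_bp"]),
                    "end_bp": int(gr["end_bp"]),
                    "lead_snp_bp": lead,
                    "distance_bp": dist,
                    "traits": ",".join(r.traits),
                }
            )
    return pd.DataFrame(rows)


def export_manhattan(
    effects: pd.DataFrame,
    snp_map: pd.DataFrame,
    threshold: BonferroniThreshold | None = None,
    path=None,
    plot_path=None,
) -> pd.DataFrame:
    """Plot-ready table: chrom, bp, -log10 p and a cumulative genome coordinate.

    The cumulative coordinate lays chromosomes end to end in map order.
    When ``path`` is given the table is written as TSV with the threshold in
    a header comment; ``plot_path`` additionally renders a minimal
    matplotlib figure.
    """
    if len(effects) != len(snp_map):
        raise ValueError("effects and SNP map are not aligned")
    df = pd.DataFrame(
        {
            "snp_id": effects["snp_id"].to_numpy(),
            "chrom": snp_map["chrom"].astype(str).to_numpy(),
            "bp": snp_map["pos"].to_numpy(),
            "neg_log10_p": effects["neg_log10_p"].to_numpy()
            if "neg_log10_p" in effects.columns
            else np.nan,
        }
    )
    cum = np.zeros(len(df), dtype=np.int64)
    offset = 0
    for chrom, grp in df.groupby("chrom", sort=False):
        cum[grp.index] = grp["bp"].to_numpy() + offset
        offset += int(grp["bp"].max()) + 1
    df["cum_bp"] = cum
    if path is not None:
        with open(path, "w") as fh:
            if threshold is not None:
                fh.write(
                    f"# bonferroni_p={threshold.p_threshold!r}"
                    f" neg_log10={threshold.neg_log10_display}\n"
                )
            df.to_csv(fh, sep="\t", index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 3))
        for i, (chrom, grp) in enumerate(df.groupby("chrom", sort=False)):
            ax.scatter(grp["cum_bp"], grp["neg_log10_p"], s=4,
                       color="steelblue" if i % 2 == 0 else "grey")
        if threshold is not None:
            ax.axhline(threshold.neg_log10, color="red", lw=0.8)
        ax.set_xlabel("genome position")
        ax.set_ylabel("-log10 p")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df
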