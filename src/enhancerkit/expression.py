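"""Expression normalization and enhancer/SE-to-gene integration.

Counts are normalized with the trimmed mean of M-values (TMM): gene-wise
log2 ratios against a reference sample are trimmed (30% on M, 5% on A) and
combined with inverse-variance weights; the exponentiated mean is the
normalization factor. Normalized expression in "A.U." is TMM-scaled counts
per million, which makes the 100 A.U. expression floor library-size-free.
TPM divides counts by exonic gene length before scaling to one million.

Differentially expressed genes follow the two-sample rule: normalized
coverage >= 10 in either condition and linear fold change >= 1.5 in either
direction (the two-sample design has no replicates, hence no test).

Two distance rules link regulatory regions to genes: differential enhancers
are assigned to every DE gene whose TSS lies within +-250 kb of the
enhancer; SEs and TEs are mapped ROSE-style to the single closest expressed
gene (> 100 A.U.) with TSS within +-50 kb of the region center, with SE
links overriding TE links and unclaimed expressed genes labeled
"no_enhancer".
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, IntervalSet

__all__ = [
    "tmm_factors",
    "tmm_cpm",
    "tpm",
    "normalize_expression",
    "call_de_genes",
    "assign_enhancers_to_genes",
    "map_nearest_genes_rose",
    "contribution_summary",
    "nearest_rank_correlation",
]


def _factor_quantile(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.quantile(counts, p, axis=0) / lib


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    n_o, n_r = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_o) / (ref / n_r))
        abs_e = (np.log2(obs / n_o) + np.log2(ref / n_r)) / 2.0
        v = (n_o - obs) / (n_o * obs) + (n_r - ref) / (n_r * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if len(log_r) == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = len(log_r)
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    keep = (
        (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    )
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, ref_column: str | None = None) -> pd.Series:
    """Per-sample TMM normalization factors, centered to geometric mean 1.

    The reference sample is the column whose 75th-percentile count fraction
    is closest to the mean across samples (unless given explicitly).
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    if ref_column is None:
        f75 = _factor_quantile(X, lib)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_column)
    ref = X[:, ref_idx]
    factors = np.array([_tmm_pair(X[:, j], ref) for j in range(X.shape[1])])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def tmm_cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """TMM-scaled counts per million — the normalized "A.U." unit."""
    if factors is None:
        factors = tmm_factors(counts)
    eff_lib = counts.sum(axis=0) * factors
    return counts / eff_lib * 1e6


def tpm(counts: pd.DataFrame | pd.Series, gene_lengths) -> pd.DataFrame | pd.Series:
    """Transcripts per million: per-length rates scaled to sum to 10^6."""
    lengths = np.asarray(gene_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if isinstance(counts, pd.Series):
        rate = counts.to_numpy(dtype=float) / lengths
        total = rate.sum()
        if total <= 0:
            raise ValueError("zero total expression")
        return pd.Series(rate / total * 1e6, index=counts.index, name=counts.name)
    rate = counts.to_numpy(dtype=float) / lengths[:, None]
    total = rate.sum(axis=0)
    if (total <= 0).any():
        raise ValueError("zero total expression in a sample")
    return pd.DataFrame(rate / total * 1e6, index=counts.index,
                        columns=counts.columns)


def normalize_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """From a (gene_id, length, count_ctrl, count_trt) table, add TMM A.U.,
    TPM and the log2 fold change (with a +1 pseudocount on A.U.)."""
    counts = expr[["count_ctrl", "count_trt"]]
    au = tmm_cpm(counts)
    out = expr.copy()
    out["au_ctrl"] = au["count_ctrl"]
    out["au_trt"] = au["count_trt"]
    t = tpm(counts, expr["length"])
    out["tpm_ctrl"] = t["count_ctrl"]
    out["tpm_trt"] = t["count_trt"]
    out["log2fc"] = np.log2((out["au_trt"] + 1.0) / (out["au_ctrl"] + 1.0))
    return out


def call_de_genes(
    expr: pd.DataFrame, min_coverage: float = 10.0, min_fc: float = 1.5
) -> pd.DataFrame:
    """Two-sample DE rule: normalized coverage >= min_coverage in either
    sample and linear fold change >= min_fc in either direction. Adds
    boolean ``de`` and ``direction`` in {up, down, none}."""
    out = expr.copy()
    ctrl = out["au_ctrl"].to_numpy(dtype=float)
    trt = out["au_trt"].to_numpy(dtype=float)
    covered = (ctrl >= min_coverage) | (trt >= min_coverage)
    with np.errstate(divide="ignore", invalid="ignore"):
        up = trt >= min_fc * ctrl
        down = ctrl >= min_fc * trt
    de = covered & (up | down)
    out["de"] = de
    out["direction"] = np.where(de & up, "up", np.where(de & down, "down", "none"))
    return out


def _tss_arrays(genes: Sequence[GeneModel]):
    return (
        np.array([g.chrom for g in genes]),
        np.array([g.tss for g in genes], dtype=np.int64),
        np.array([g.gene_id for g in genes], dtype=object),
    )


def assign_enhancers_to_genes(
    enhancers: pd.DataFrame,
    genes: Sequence[GeneModel],
    window: int = 250_000,
) -> pd.DataFrame:
    """All (enhancer, gene) pairs with the gene TSS within +-window of the
    enhancer boundaries; distance is 0 for a TSS inside the enhancer, else
    base pairs to the nearest boundary. Many-to-many by design."""
    g_chrom, g_tss, g_id = _tss_arrays(genes)
    rows = []
    for i, r in enhancers.reset_index(drop=True).iterrows():
        near = (
            (g_chrom == r["chrom"])
            & (g_tss >= r["start"] - window)
            & (g_tss < r["end"] + window)
        )
        for j in np.flatnonzero(near):
            dist = int(max(0, r["start"] - g_tss[j], g_tss[j] - (r["end"] - 1)))
            rows.append(
                {
                    "enhancer_idx": i,
                    "chrom": r["chrom"],
                    "start": int(r["start"]),
                    "end": int(r["end"]),
                    "gene_id": g_id[j],
                    "distance": dist,
                    "link_type": "window_250kb" if window == 250_000
                    else f"window_{window}",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["enhancer_idx", "chrom", "start", "end", "gene_id",
                 "distance", "link_type"],
    )


def map_nearest_genes_rose(
    ses: pd.DataFrame,
    tes: pd.DataFrame,
    genes: Sequence[GeneModel],
    expr: pd.DataFrame,
    window: int = 50_000,
    expression_floor: float = 100.0,
) -> pd.DataFrame:
    """ROSE-style nearest-gene mapping of SEs and TEs.

    Each region maps to the single closest expressed gene (A.U. above the
    floor in either condition) whose TSS is within +-window of the region
    center; distance ties break to the lexicographically lower gene_id. A
    gene claimed by both an SE and a TE keeps only the SE link; expressed
    genes with no SE/TE center within the window are "no_enhancer" rows.
    Returns one row per link plus the no_enhancer gene rows.
    """
    au = expr.set_index("gene_id")[["au_ctrl", "au_trt"]]
    expressed = au.max(axis=1) > expression_floor
    keep_ids = set(au.index[expressed])
    kept = [g for g in genes if g.gene_id in keep_ids]
    g_chrom, g_tss, g_id = _tss_arrays(kept) if kept else (
        np.array([]), np.array([], dtype=np.int64), np.array([], dtype=object))

    def nearest_links(regions: pd.DataFrame, link_type: str) -> pd.DataFrame:
        rows = []
        for i, r in regions.reset_index(drop=True).iterrows():
            center = (int(r["start"]) + int(r["end"])) // 2
            mask = g_chrom == r["chrom"]
            if not mask.any():
                continue
            dist = np.abs(g_tss[mask] - center)
            within = dist <= window
            if not within.any():
                continue
            cand_ids = g_id[mask][within]
            cand_dist = dist[within]
            best = np.lexsort((cand_ids, cand_dist))[0]
            rows.append(
                {
                    "region_idx": i,
                    "chrom": r["chrom"],
                    "start": int(r["start"]),
                    "end": int(r["end"]),
                    "gene_id": cand_ids[best],
                    "distance": int(cand_dist[best]),
                    "link_type": link_type,
                }
            )
        return pd.DataFrame(
            rows, columns=["region_idx", "chrom", "start", "end", "gene_id",
                           "distance", "link_type"])

    se_links = nearest_links(ses, "nearest_50kb_SE")
    te_links = nearest_links(tes, "nearest_50kb_TE")
    se_genes = set(se_links["gene_id"])
    te_links = te_links[~te_links["gene_id"].isin(se_genes)]  # SE priority
    claimed = se_genes | set(te_links["gene_id"])
    no_enh = pd.DataFrame(
        {
            "region_idx": -1,
            "chrom": pd.NA,
            "start": pd.NA,
            "end": pd.NA,
            "gene_id": sorted(keep_ids - claimed),
            "distance": pd.NA,
            "link_type": "no_enhancer",
        }
    )
    return pd.concat([se_links, te_links, no_enh], ignore_index=True)


def contribution_summary(
    links: pd.DataFrame,
    expr: pd.DataFrame,
    se_classes: pd.Series | dict,
    fc_partition_threshold: float = 1.0,
) -> dict:
    """Cumulative-expression summary of SE-associated genes.

    percent_change = 100 * (sum A.U. treated - sum A.U. control) / sum A.U.
    control over genes linked to SEs; per-SE-class contributions are in
    percentage points of the same denominator and sum exactly to the total.
    Also counts up/down SE-associated genes at |log2FC| > threshold.
    """
    se_classes = pd.Series(se_classes)
    se_links = links[links["link_type"] == "nearest_50kb_SE"].copy()
    se_links["se_class"] = se_links["region_idx"].map(se_classes)
    au = expr.set_index("gene_id")
    gene_class = (
        se_links.drop_duplicates("gene_id").set_index("gene_id")["se_class"]
    )
    se_genes = gene_class.index
    ctrl_total = float(au.loc[se_genes, "au_ctrl"].sum())
    trt_total = float(au.loc[se_genes, "au_trt"].sum())
    if ctrl_total <= 0:
        raise ValueError("zero total control expression over SE genes")
    percent_change = 100.0 * (trt_total - ctrl_total) / ctrl_total
    contributions = {}
    for cls in sorted(gene_class.dropna().unique()):
        ids = gene_class.index[gene_class == cls]
        delta = float(
            au.loc[ids, "au_trt"].sum() - au.loc[ids, "au_ctrl"].sum()
        )
        contributions[str(cls)] = 100.0 * delta / ctrl_total
    log2fc = np.log2(
        (au.loc[se_genes, "au_trt"] + 1.0) / (au.loc[se_genes, "au_ctrl"] + 1.0)
    )
    return {
        "se_gene_total_au_ctrl": ctrl_total,
        "se_gene_total_au_trt": trt_total,
        "percent_change": percent_change,
        "class_contributions": contributions,
        "n_se_genes_up": int((log2fc > fc_partition_threshold).sum()),
        "n_se_genes_down": int((log2fc < -fc_partition_threshold).sum()),
    }


def nearest_rank_correlation(
    regions: pd.DataFrame,
    genes: Sequence[GeneModel],
    expr: pd.DataFrame,
    ranks: Sequence[int] = (1, 2, 3),
    signal_col: str = "signal_log2fc",
    min_points: int = 3,
) -> pd.DataFrame:
    """Spearman correlation between region activity change and expression
    change of the 1st/2nd/3rd nearest expressed genes (center-to-TSS)."""
    au = expr.set_index("gene_id")
    g_chrom, g_tss, g_id = _tss_arrays(genes)
    per_rank: dict[int, list[tuple[float, float]]] = {k: [] for k in ranks}
    for _, r in regions.iterrows():
        center = (int(r["start"]) + int(r["end"])) // 2
        mask = g_chrom == r["chrom"]
        if not mask.any():
            continue
        dist = np.abs(g_tss[mask] - center)
        ids = g_id[mask]
        order = np.lexsort((ids, dist))
        for k in ranks:
            if k <= len(order):
                gid = ids[order[k - 1]]
                if gid in au.index:
                    per_rank[k].append(
                        (float(r[signal_col]), float(au.loc[gid, "log2fc"]))
                    )
    rows = []
    for k in ranks:
        pairs = per_rank[k]
        if len(pairs) < min_points:
            rho = np.nan
        else:
            arr = np.asarray(pairs)
            rho = float(stats.spearmanr(arr[:, 0], arr[:, 1]).statistic)
        rows.append({"rank": k, "n": len(pairs), "spearman_rho": rho})
    return pd.DataFrame(rows)
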