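"""Enhancer definition and differential H3K27ac enrichment testing.

The procedure: merge per-sample H3K27ac peaks and keep regions supported by
at least ``min_support`` of the samples that also overlap an equally
supported merged H3K4me1 region (co-occupancy); discard regions touching
promoters (TSS +- 1 kb), exons, or H3K4me3 peaks; score each enhancer in
each ChIP sample as ``log2((Count_ChIP + 1) / (Count_input + 1))`` with both
counts scaled to one million fragments; quantile-normalize the
enhancer x sample matrix; test treated vs control per enhancer with an
empirical-Bayes moderated t statistic; adjust with Benjamini-Hochberg; and
label classes (up / down / unaffected background / de-novo gained or lost).

The moderated test shrinks per-enhancer sample variances s^2 toward a prior
s0^2 with prior degrees of freedom d0:

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t = logFC / (s_tilde * sqrt(1/n1 + 1/n2)),   t ~ Student(d + d0)

(d0, s0^2) are estimated by moment matching on log s^2 (digamma/trigamma
inversion). d0 = 0 recovers the ordinary pooled-variance t; d0 = inf pools
all enhancers to a single shared variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .intervals import (
    GeneModel,
    IntervalSet,
    SampleTrack,
    count_support,
    exon_union,
    merge_intervals,
    promoter_windows,
    scaled_region_counts,
)

__all__ = [
    "EnhancerCatalog",
    "EnrichmentMatrix",
    "EBayesParams",
    "call_candidate_enhancers",
    "filter_regulatory",
    "compute_enrichment",
    "quantile_normalize",
    "moderated_two_group_test",
    "bh_adjust",
    "classify_differential",
    "classify_de_novo",
    "differential_enhancer_table",
]

CONTROL = "control"
TREATED = "treated"


@dataclass
class EnhancerCatalog:
    """Co-occupied, regulatory-filtered enhancer regions with provenance."""

    enhancers: IntervalSet
    ac_support: np.ndarray
    n_candidates: int
    n_removed_promoter: int
    n_removed_exon: int
    n_removed_k4me3: int

    def __len__(self) -> int:
        return len(self.enhancers)


def call_candidate_enhancers(
    ac_peaks: Sequence[IntervalSet],
    me1_peaks: Sequence[IntervalSet],
    min_support: int = 2,
) -> tuple[IntervalSet, np.ndarray]:
    """Merged H3K27ac regions with >= min_support sample support that overlap
    a merged H3K4me1 region with >= min_support support.

    The enhancer footprint is the H3K27ac merged region; H3K4me1 only gates
    membership (>= 1 bp overlap). Returns (regions, H3K27ac support counts).
    """
    if len(ac_peaks) != len(me1_peaks):
        raise ValueError(
            f"sample count mismatch: {len(ac_peaks)} H3K27ac vs "
            f"{len(me1_peaks)} H3K4me1 peak sets"
        )
    ac_merged = merge_intervals(IntervalSet.concat(ac_peaks))
    ac_supp = count_support(ac_merged, ac_peaks)
    ac_keep = ac_merged.subset(ac_supp >= min_support)
    ac_keep_supp = ac_supp[ac_supp >= min_support]

    me1_merged = merge_intervals(IntervalSet.concat(me1_peaks))
    me1_supp = count_support(me1_merged, me1_peaks)
    me1_keep = me1_merged.subset(me1_supp >= min_support)

    has_me1 = ac_keep.overlaps_any(me1_keep)
    return ac_keep.subset(has_me1), ac_keep_supp[has_me1]


def filter_regulatory(
    candidates: IntervalSet,
    genes: Sequence[GeneModel],
    k4me3_peaks: IntervalSet,
    promoter_flank: int = 1000,
    ac_support: np.ndarray | None = None,
) -> EnhancerCatalog:
    """Drop candidates overlapping promoters (TSS +- flank), exons of known
    genes, or H3K4me3 peaks (potential promoters), by >= 1 bp."""
    if ac_support is None:
        ac_support = np.zeros(len(candidates), dtype=np.int64)
    in_prom = candidates.overlaps_any(promoter_windows(genes, promoter_flank))
    in_exon = candidates.overlaps_any(exon_union(genes))
    in_k4me3 = candidates.overlaps_any(k4me3_peaks)
    keep = ~(in_prom | in_exon | in_k4me3)
    return EnhancerCatalog(
        enhancers=candidates.subset(keep),
        ac_support=np.asarray(ac_support)[keep],
        n_candidates=len(candidates),
        n_removed_promoter=int(in_prom.sum()),
        n_removed_exon=int((in_exon & ~in_prom).sum()),
        n_removed_k4me3=int((in_k4me3 & ~in_prom & ~in_exon).sum()),
    )


@dataclass
class EnrichmentMatrix:
    """Enhancer x sample log2 ChIP/input enrichment with raw scaled counts."""

    regions: IntervalSet
    E: pd.DataFrame  # rows: enhancers, columns: sample_ids
    chip_counts: pd.DataFrame
    input_counts: pd.DataFrame
    conditions: pd.Series  # sample_id -> condition
    normalized: bool = False


def compute_enrichment(
    regions: IntervalSet,
    chip_tracks: Sequence[SampleTrack],
    input_tracks: Sequence[SampleTrack],
    pairing: Mapping[str, str] | None = None,
) -> EnrichmentMatrix:
    """E[i, s] = log2((Count_ChIP + 1)/(Count_input + 1)), per-million scaled.

    ``pairing`` maps chip sample_id -> input sample_id; when omitted each
    chip sample is paired with the input track of its condition and
    replicate (falling back to any input of its condition).
    """
    inputs_by_id = {t.sample_id: t for t in input_tracks}
    inputs_by_cond: dict[str, SampleTrack] = {}
    inputs_by_cond_rep: dict[tuple[str, int], SampleTrack] = {}
    for t in input_tracks:
        inputs_by_cond.setdefault(t.condition, t)
        inputs_by_cond_rep.setdefault((t.condition, t.replicate), t)

    chip, inp, conds = {}, {}, {}
    for track in chip_tracks:
        if pairing is not None:
            key = pairing.get(track.sample_id)
            if key is None or key not in inputs_by_id:
                raise ValueError(
                    f"no input pairing for ChIP sample {track.sample_id}"
                )
            paired = inputs_by_id[key]
        else:
            paired = inputs_by_cond_rep.get(
                (track.condition, track.replicate),
                inputs_by_cond.get(track.condition),
            )
            if paired is None:
                raise ValueError(
                    f"no input track for condition {track.condition!r} "
                    f"(ChIP sample {track.sample_id})"
                )
        chip[track.sample_id] = scaled_region_counts(regions, track)
        inp[track.sample_id] = scaled_region_counts(regions, paired)
        conds[track.sample_id] = track.condition

    chip_df = pd.DataFrame(chip)
    inp_df = pd.DataFrame(inp)
    E = np.log2((chip_df + 1.0) / (inp_df + 1.0))
    return EnrichmentMatrix(
        regions=regions, E=E, chip_counts=chip_df, input_counts=inp_df,
        conditions=pd.Series(conds), normalized=False,
    )


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of per-rank row means
    of the sorted columns; ties receive the mean of their ranks' reference
    values. Within-column rank order is preserved."""
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: single column, returned unchanged")
        return matrix.copy()
    X = matrix.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        vals = np.empty_like(ref)
        vals[order] = ref
        # average reference values over tied input values
        s = pd.Series(vals).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class EBayesParams:
    """Prior for the moderated t: d0 prior df (inf allowed), s0_sq prior
    variance, d residual df per feature."""

    d0: float
    s0_sq: float
    d: float


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_ebayes_params(s_sq: np.ndarray, d: float) -> EBayesParams:
    """Moment-match an F(d, d0)-scaled prior to the observed sample variances
    via the mean and variance of log s^2. Non-finite moment estimates fall
    back to d0 = inf (a single shared variance)."""
    s_sq = np.asarray(s_sq, dtype=float)
    ok = np.isfinite(s_sq) & (s_sq > 0)
    if ok.sum() < 2:
        pooled = float(np.nanmean(s_sq[ok])) if ok.any() else 1.0
        return EBayesParams(d0=np.inf, s0_sq=max(pooled, 1e-300), d=d)
    e = np.log(s_sq[ok]) - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        if not np.isfinite(d0):
            d0 = np.inf
    else:
        d0 = np.inf
    if np.isfinite(d0):
        s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        s0 = np.exp(emean)
    return EBayesParams(d0=float(d0), s0_sq=float(s0), d=float(d))


def moderated_two_group_test(
    matrix: pd.DataFrame,
    conditions: Sequence[str],
    params: EBayesParams | str = "estimate",
    control_label: str = CONTROL,
    treated_label: str = TREATED,
) -> pd.DataFrame:
    """Per-feature treated-vs-control moderated t test on a feature x sample
    matrix. Returns logFC, t, p, mean_ctrl_E, mean_trt_E (params in attrs).

    Features with zero residual variance get an undefined statistic when
    d0 = 0 (reported as NaN and excluded downstream from BH).
    """
    conditions = np.asarray(list(conditions))
    if len(conditions) != matrix.shape[1]:
        raise ValueError("conditions length must match number of columns")
    ctrl = matrix.loc[:, conditions == control_label].to_numpy(dtype=float)
    trt = matrix.loc[:, conditions == treated_label].to_numpy(dtype=float)
    n1, n2 = ctrl.shape[1], trt.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    mean_c = ctrl.mean(axis=1)
    mean_t = trt.mean(axis=1)
    logfc = mean_t - mean_c
    d = float(n1 + n2 - 2)
    rss = ((ctrl - mean_c[:, None]) ** 2).sum(axis=1) + (
        (trt - mean_t[:, None]) ** 2
    ).sum(axis=1)
    s_sq = rss / d

    if isinstance(params, str):
        if params != "estimate":
            raise ValueError(f"unknown params mode {params!r}")
        params = estimate_ebayes_params(s_sq, d)
    d0, s0_sq = params.d0, params.s0_sq

    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + d * s_sq) / (d0 + d)
        df_total = d + d0
    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, np.nan)
        # zero logFC over zero se is a genuinely uninformative feature
        t = np.where((se == 0) & (logfc == 0), np.nan, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p": p,
            "mean_ctrl_E": mean_c,
            "mean_trt_E": mean_t,
        },
        index=matrix.index,
    )
    out.attrs["ebayes"] = params
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values; NaN p stay NaN."""
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def classify_differential(
    table: pd.DataFrame,
    logfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    background_band: float = 1.05,
) -> pd.DataFrame:
    """Label classes: up (logFC >= threshold, q < q_threshold), down
    (mirrored), unaffected_background (linear fold within the band), other.

    ``logfc_threshold`` is in log2 units (1.0 means linear fold 2);
    ``background_band`` is a linear fold (1.05 per the lowest-difference
    background set). Adds q if absent; NaN statistics land in "other".
    """
    out = table.copy()
    if "q" not in out.columns:
        out["q"] = bh_adjust(out["p"].to_numpy())
    logfc = out["logFC"].to_numpy(dtype=float)
    q = out["q"].to_numpy(dtype=float)
    sig = ~np.isnan(q) & (q < q_threshold)
    cls = np.full(len(out), "other", dtype=object)
    cls[np.abs(logfc) <= np.log2(background_band)] = "unaffected_background"
    cls[sig & (logfc >= logfc_threshold)] = "up"
    cls[sig & (logfc <= -logfc_threshold)] = "down"
    cls[np.isnan(out["t"].to_numpy(dtype=float))] = "other"
    out["class"] = cls
    return out


def classify_de_novo(
    table: pd.DataFrame,
    gained_hi: float = 1.5,
    flat_lo: float = 1.1,
    scale: str = "log2",
) -> pd.DataFrame:
    """Refine up/down labels into de-novo gained/lost by absolute enrichment.

    An up enhancer with mean treated enrichment > gained_hi and mean control
    < flat_lo becomes de_novo_gained; a down enhancer with the mirror
    pattern becomes de_novo_lost. Thresholds apply to the log2 enrichment E
    by default; ``scale="linear"`` applies them to 2**E instead (the
    alternative reading of "ChIP enrichment signals").
    """
    if scale not in ("log2", "linear"):
        raise ValueError("scale must be 'log2' or 'linear'")
    out = table.copy()
    ctrl = out["mean_ctrl_E"].to_numpy(dtype=float)
    trt = out["mean_trt_E"].to_numpy(dtype=float)
    if scale == "linear":
        ctrl, trt = 2.0 ** ctrl, 2.0 ** trt
    cls = out["class"].to_numpy(dtype=object).copy()
    up = cls == "up"
    down = cls == "down"
    cls[up & (trt > gained_hi) & (ctrl < flat_lo)] = "de_novo_gained"
    cls[down & (trt < flat_lo) & (ctrl > gained_hi)] = "de_novo_lost"
    out["class"] = cls
    return out


def differential_enhancer_table(
    catalog: EnhancerCatalog,
    chip_tracks: Sequence[SampleTrack],
    input_tracks: Sequence[SampleTrack],
    pairing: Mapping[str, str] | None = None,
    params: EBayesParams | str = "estimate",
    logfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    background_band: float = 1.05,
    de_novo_hi: float = 1.5,
    de_novo_lo: float = 1.1,
    de_novo_scale: str = "log2",
) -> pd.DataFrame:
    """Full differential pipeline: enrichment -> quantile normalization ->
    moderated t -> BH -> class labels. Returns one row per enhancer with
    coordinates, logFC, t, p, q, class and mean enrichments."""
    mat = compute_enrichment(catalog.enhancers, chip_tracks, input_tracks, pairing)
    E = quantile_normalize(mat.E)
    table = moderated_two_group_test(E, mat.conditions[E.columns], params)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table = classify_differential(
        table, logfc_threshold, q_threshold, background_band
    )
    table = classify_de_novo(table, de_novo_hi, de_novo_lo, de_novo_scale)
    coords = catalog.enhancers.df[["chrom", "start", "end"]].reset_index(drop=True)
    out = pd.concat([coords, table.reset_index(drop=True)], axis=1)
    out.attrs.update(table.attrs)
    return out
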