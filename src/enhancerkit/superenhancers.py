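"""ROSE-style super-enhancer calling and differential SE classification.

Enhancers within 12.5 kb of each other (end-to-start distance) are stitched
into candidate regions; each stitched region is scored by its
background-subtracted ChIP signal in reads per million (replicates averaged
after per-million scaling, input subtracted, floored at zero); regions are
ranked by signal and the super-enhancer cutoff is the tangency point where a
slope-1 line touches the unit-scaled rank curve — regions strictly above the
cutoff signal are SEs, the rest typical enhancers (TEs).

Differential classification evaluates the union of SE spans from the two
conditions (overlapping spans merged, so each locus is classified once):
fold change (signal_trt + eps)/(signal_ctrl + eps) >= 2 is gained, <= 0.5
lost, anything else unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet, SampleTrack, scaled_region_counts

__all__ = [
    "StitchedRegion",
    "RoseRanking",
    "stitch",
    "background_subtracted_signal",
    "region_signals",
    "rose_cutoff",
    "call_super_enhancers",
    "differential_super_enhancers",
    "se_summary_stats",
]

log = logging.getLogger(__name__)

DEFAULT_STITCH_GAP = 12_500
DEFAULT_EPSILON = 0.1  # rpm pseudo-signal in SE fold changes


@dataclass
class StitchedRegion:
    chrom: str
    start: int
    end: int
    constituents: IntervalSet

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


def stitch(enhancers: IntervalSet, gap: int = DEFAULT_STITCH_GAP) -> list[StitchedRegion]:
    """Chain enhancers whose end-to-start distance is <= gap; output regions
    are separated by > gap. Order of input does not matter."""
    if not len(enhancers):
        return []
    df = enhancers.df.sort_values(["chrom", "start", "end"], kind="mergesort")
    out: list[StitchedRegion] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        run_end = np.maximum.accumulate(ends)
        new_block = np.empty(len(starts), dtype=bool)
        new_block[0] = True
        new_block[1:] = starts[1:] - run_end[:-1] > gap
        block = np.cumsum(new_block) - 1
        for b in range(block[-1] + 1):
            m = block == b
            cons = IntervalSet(sub[m].reset_index(drop=True))
            out.append(
                StitchedRegion(
                    chrom=str(chrom),
                    start=int(starts[m].min()),
                    end=int(ends[m].max()),
                    constituents=cons,
                )
            )
    return out


def _spans(regions: Sequence[StitchedRegion]) -> IntervalSet:
    return IntervalSet(
        pd.DataFrame(
            {
                "chrom": [r.chrom for r in regions],
                "start": [r.start for r in regions],
                "end": [r.end for r in regions],
            }
        )
    )


def region_signals(
    spans: IntervalSet,
    chip_tracks: Sequence[SampleTrack],
    input_tracks: Sequence[SampleTrack] | None,
) -> np.ndarray:
    """Background-subtracted rpm over each span: replicate-averaged scaled
    ChIP minus replicate-averaged scaled input, floored at zero. A missing
    input track falls back to raw ChIP rpm with a logged warning."""
    chip = np.mean(
        [scaled_region_counts(spans, t) for t in chip_tracks], axis=0
    )
    if not input_tracks:
        log.warning("no input track: using unsubtracted ChIP rpm as signal")
        return chip
    inp = np.mean(
        [scaled_region_counts(spans, t) for t in input_tracks], axis=0
    )
    return np.maximum(0.0, chip - inp)


def background_subtracted_signal(
    region: StitchedRegion,
    chip: SampleTrack | Sequence[SampleTrack],
    input_track: SampleTrack | Sequence[SampleTrack] | None,
) -> float:
    """Scalar convenience wrapper of :func:`region_signals` for one region."""
    chips = [chip] if isinstance(chip, SampleTrack) else list(chip)
    inputs = (
        None
        if input_track is None
        else [input_track] if isinstance(input_track, SampleTrack) else list(input_track)
    )
    spans = _spans([region])
    return float(region_signals(spans, chips, inputs)[0])


def rose_cutoff(signals: np.ndarray) -> tuple[float, np.ndarray]:
    """Slope-1 tangency cutoff on the ascending unit-scaled rank curve.

    With x = rank/(n-1) and y = (signal - min)/(max - min), the cutoff index
    is argmax(x - y) (ties broken to the highest-signal index); SE means
    signal strictly above the cutoff signal. A flat signal vector yields
    zero SEs.
    """
    signals = np.asarray(signals, dtype=float)
    n = len(signals)
    if n < 2:
        return (float(signals[0]) if n else np.nan), np.zeros(n, dtype=bool)
    order = np.argsort(signals, kind="mergesort")
    s = signals[order]
    lo, hi = s[0], s[-1]
    if hi == lo:
        log.info("rose_cutoff: flat signal vector, zero SEs")
        return float(hi), np.zeros(n, dtype=bool)
    x = np.arange(n) / (n - 1)
    y = (s - lo) / (hi - lo)
    d = x - y
    cut_idx = n - 1 - int(np.argmax(d[::-1]))  # last index attaining the max
    cutoff = float(s[cut_idx])
    return cutoff, signals > cutoff


@dataclass
class RoseRanking:
    """Stitched regions ranked ascending by signal, with the SE cutoff."""

    table: pd.DataFrame  # chrom,start,end,n_constituents,signal,rank,is_se
    cutoff_signal: float
    regions: list[StitchedRegion] = field(default_factory=list)

    @property
    def n_se(self) -> int:
        return int(self.table["is_se"].sum())

    @property
    def se_spans(self) -> IntervalSet:
        return IntervalSet(
            self.table.loc[self.table["is_se"], ["chrom", "start", "end"]]
            .reset_index(drop=True)
        )


def call_super_enhancers(
    enhancers: IntervalSet,
    chip_tracks: Sequence[SampleTrack],
    input_tracks: Sequence[SampleTrack] | None,
    gap: int = DEFAULT_STITCH_GAP,
) -> RoseRanking:
    """stitch -> background-subtracted signal -> rank-curve cutoff.

    ``enhancers`` is the H3K27ac/H3K4me1 catalog, or a BRD4 peak set for
    BRD4-defined SEs; tracks are the condition's ChIP replicates and inputs.
    """
    regions = stitch(enhancers, gap)
    if not regions:
        empty = pd.DataFrame(
            columns=["chrom", "start", "end", "n_constituents", "signal",
                     "rank", "is_se"]
        )
        return RoseRanking(table=empty, cutoff_signal=np.nan, regions=[])
    spans = _spans(regions)
    signal = region_signals(spans, chip_tracks, input_tracks)
    cutoff, is_se = rose_cutoff(signal)
    table = spans.df.copy()
    table["n_constituents"] = [r.n_constituents for r in regions]
    table["signal"] = signal
    table["rank"] = pd.Series(signal).rank(method="first").astype(int)
    table["is_se"] = is_se
    table = table.sort_values("rank", kind="mergesort").reset_index(drop=True)
    return RoseRanking(table=table, cutoff_signal=cutoff, regions=regions)


def differential_super_enhancers(
    ctrl: RoseRanking,
    trt: RoseRanking,
    ctrl_chip: Sequence[SampleTrack],
    ctrl_input: Sequence[SampleTrack] | None,
    trt_chip: Sequence[SampleTrack],
    trt_input: Sequence[SampleTrack] | None,
    epsilon: float = DEFAULT_EPSILON,
    gained_fc: float = 2.0,
    lost_fc: float = 0.5,
) -> pd.DataFrame:
    """Classify every locus that is an SE in at least one condition.

    SE spans from both conditions are merged into a single evaluation
    universe; per-condition background-subtracted signals are recomputed on
    the merged spans and fc = (signal_trt + eps)/(signal_ctrl + eps) drives
    the gained (>= gained_fc) / lost (<= lost_fc) / unchanged labels.
    """
    universe = IntervalSet.concat([ctrl.se_spans, trt.se_spans]).merge()
    if not len(universe):
        return pd.DataFrame(
            columns=["chrom", "start", "end", "signal_ctrl", "signal_trt",
                     "fc", "class"]
        )
    sig_c = region_signals(universe, ctrl_chip, ctrl_input)
    sig_t = region_signals(universe, trt_chip, trt_input)
    fc = (sig_t + epsilon) / (sig_c + epsilon)
    cls = np.where(fc >= gained_fc, "gained",
                   np.where(fc <= lost_fc, "lost", "unchanged"))
    out = universe.df.copy()
    out["signal_ctrl"] = sig_c
    out["signal_trt"] = sig_t
    out["fc"] = fc
    out["class"] = cls
    return out


def se_summary_stats(diff_table: pd.DataFrame) -> pd.DataFrame:
    """Per class: median length (kb), median signal (rpm, per condition) and
    median signal density (rpm/bp), as summarized for gained/lost SEs."""
    rows = []
    for cls, sub in diff_table.groupby("class"):
        length = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        rows.append(
            {
                "class": cls,
                "n": len(sub),
                "median_length_kb": float(np.median(length) / 1e3),
                "median_signal_ctrl_rpm": float(sub["signal_ctrl"].median()),
                "median_signal_trt_rpm": float(sub["signal_trt"].median()),
                "median_density_ctrl_rpm_per_bp": float(
                    np.median(sub["signal_ctrl"] / length)
                ),
                "median_density_trt_rpm_per_bp": float(
                    np.median(sub["signal_trt"] / length)
                ),
            }
        )
    return pd.DataFrame(rows)
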