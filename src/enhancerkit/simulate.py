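"""Seeded synthetic experiments with planted truth.

The generator emulates the statistical structure the analysis assumes — a
two-condition, two-replicate ChIP design over a toy genome — so every
downstream stage is testable without external data:

* a toy genome (default 2 chromosomes x 50 Mb) populated with well-separated
  singleton enhancers, clustered enhancers (super-enhancer seeds whose
  constituents sit within the 12.5 kb stitching distance of each other),
  genes, decoy regions and lncRNAs;
* per-sample peak sets: every planted enhancer gets peaks (with jittered
  boundaries) in both replicates of each condition where it is active, so
  the >= 2-of-4 support rule retains it, plus spurious single-sample peaks
  that the rule must discard, plus decoy regions that only the promoter /
  exon / H3K4me3 filters can remove;
* fragment placements: uniform genome-wide background (expected
  ``background_rate`` fragments per 2 kb of region) in every track, plus
  Poisson or negative-binomial signal fragments at active enhancers. Signal
  magnitudes are solved per region so the *expected* log2 ChIP/input
  enrichment hits the planted targets exactly: an active enhancer sits at
  its base enrichment, "up" enhancers gain ``effect_size`` log2 units in
  the treated condition, de-novo enhancers idle at a low enrichment
  (default 0.5, below the 1.1 threshold) in their inactive condition;
* an expression table whose planted log2 fold changes (+-``expr_effect``)
  follow the enhancer/SE class of the gene's linked region;
* lncRNAs, a configured fraction of which is planted on top of enhancers.

Everything is drawn from one ``numpy`` Generator seeded from the config, so
a fixed seed reproduces the experiment bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    GenomeLayout,
    IntervalSet,
    SampleTrack,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulatedExperiment",
    "simulate_experiment",
    "simulate_null_overlap",
    "place_random_intervals",
]

SLOT_BUFFER = 15_000  # bp between placed elements; > the 12.5 kb stitch gap

_DEFAULT_CLASS_FRACTIONS = {
    "up": 0.15,
    "down": 0.15,
    "unaffected": 0.50,
    "de_novo_gained": 0.10,
    "de_novo_lost": 0.10,
}
_DEFAULT_SE_CLASS_FRACTIONS = {"gained": 0.4, "lost": 0.3, "unchanged": 0.3}


def _default_genome() -> GenomeLayout:
    return GenomeLayout({"chr1": 50_000_000, "chr2": 50_000_000})


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: GenomeLayout = field(default_factory=_default_genome)
    n_genes: int = 300
    n_enhancers: int = 500
    class_fractions: dict = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_FRACTIONS))
    n_se_clusters: int = 10
    enhancers_per_cluster: int = 5
    se_class_fractions: dict = field(
        default_factory=lambda: dict(_DEFAULT_SE_CLASS_FRACTIONS))
    effect_size: float = 2.0  # planted log2 enrichment difference
    background_rate: float = 20.0  # expected input fragments per 2 kb region
    signal_rate: float = 63.0  # expected signal fragments at an active enhancer
    de_novo_low_enrichment: float = 0.5  # log2 E of a de-novo site when "off"
    cluster_signal_mult: float = 10.0  # cluster constituents vs singletons
    se_signal_ratio: float = 4.0  # treated/control signal of gained clusters
    count_noise: str = "poisson"  # or "negative_binomial"
    nb_dispersion: float = 0.1
    expr_baseline_mean: float = 300.0  # log-normal median of baseline counts
    expr_dispersion: float = 0.05  # NB dispersion of expression counts
    expr_effect: float = 1.0  # planted |log2 fc| for linked genes
    n_lncrnas: int = 100
    lncrna_overlap_fraction: float = 0.3
    enhancer_length: tuple[int, int] = (1000, 3000)
    lncrna_length: tuple[int, int] = (500, 5000)
    fragment_length: int = 200
    n_spurious_peaks: int = 100
    n_decoys: int = 20  # co-occupied regions only the exclusion filters catch
    peak_jitter: int = 100
    simulate_brd4: bool = False

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if abs(sum(self.se_class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("se_class_fractions must sum to 1")
        for name in ("background_rate", "signal_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.count_noise not in ("poisson", "negative_binomial"):
            raise ValueError("count_noise must be poisson or negative_binomial")


@dataclass
class TruthTable:
    """Planted ground truth: coordinates plus the planted class of every
    enhancer, SE cluster, gene and lncRNA."""

    enhancers: pd.DataFrame  # chrom,start,end,class,cluster_id,linked_gene
    clusters: pd.DataFrame  # cluster_id,chrom,start,end,se_class
    genes: pd.DataFrame  # gene_id,expr_class,linked_region
    lncrnas: pd.DataFrame  # lnc_id,chrom,start,end,planted_enhancer


@dataclass
class SimulatedExperiment:
    genome: GenomeLayout
    tracks: list[SampleTrack]
    genes: list[GeneModel]
    expression: pd.DataFrame  # gene_id,length,count_ctrl,count_trt
    lncrnas: IntervalSet
    truth: TruthTable
    config: SimulationConfig

    def tracks_for(self, mark: str, condition: str | None = None) -> list[SampleTrack]:
        out = [t for t in self.tracks if t.mark == mark]
        if condition is not None:
            out = [t for t in out if t.condition == condition]
        return sorted(out, key=lambda t: (t.condition, t.replicate))

    def peak_sets(self, mark: str) -> list[IntervalSet]:
        return [t.peaks for t in self.tracks_for(mark)]


# --------------------------------------------------------------------------
# placement helpers

def _alloc_counts(n: int, fractions: dict, rng: np.random.Generator) -> np.ndarray:
    """Integer class counts matching fractions (largest-remainder rounding),
    assigned to elements in shuffled order."""
    names = list(fractions)
    raw = np.array([fractions[c] * n for c in names])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    if rem > 0:
        order = np.argsort(-(raw - counts), kind="mergesort")
        counts[order[:rem]] += 1
    labels = np.repeat(names, counts)
    return labels[rng.permutation(n)] if n else np.array([], dtype=object)


class _Placer:
    """Greedy random placement of fixed-width slots with a separation buffer."""

    def __init__(self, genome: GenomeLayout, rng: np.random.Generator):
        self.genome = genome
        self.rng = rng
        self.chroms = list(genome.chrom_lengths)
        self.cursor = {c: SLOT_BUFFER for c in self.chroms}

    def place(self, width: int, extra_gap: int) -> tuple[str, int]:
        order = self.rng.permutation(len(self.chroms))
        for i in order:
            c = self.chroms[i]
            gap = SLOT_BUFFER + int(self.rng.integers(0, max(1, extra_gap)))
            pos = self.cursor[c] + gap
            if pos + width + SLOT_BUFFER <= self.genome.chrom_lengths[c]:
                self.cursor[c] = pos + width
                return c, pos
            # retry without the random extra before giving up on this chrom
            pos = self.cursor[c] + SLOT_BUFFER
            if pos + width + SLOT_BUFFER <= self.genome.chrom_lengths[c]:
                self.cursor[c] = pos + width
                return c, pos
        raise ValueError(
            "genome too small to place all requested elements with the "
            f"required {SLOT_BUFFER} bp spacing"
        )


def place_random_intervals(
    lengths: np.ndarray, genome: GenomeLayout, rng: np.random.Generator
) -> IntervalSet:
    """Place each element uniformly over its valid start positions, on a
    chromosome drawn with probability proportional to those positions."""
    lengths = np.asarray(lengths, dtype=np.int64)
    chrom_names = list(genome.chrom_lengths)
    chrom_lengths = np.array(
        [genome.chrom_lengths[c] for c in chrom_names], dtype=np.int64
    )
    valid = np.maximum(chrom_lengths[None, :] - lengths[:, None] + 1, 0)
    totals = valid.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("an element is longer than every chromosome")
    draw = rng.integers(0, totals, dtype=np.int64)
    cum = np.cumsum(valid, axis=1)
    chrom_idx = (draw[:, None] >= cum).sum(axis=1)
    prev = np.where(
        chrom_idx > 0,
        np.take_along_axis(cum, np.maximum(chrom_idx - 1, 0)[:, None], axis=1).ravel(),
        0,
    )
    start = draw - prev
    return IntervalSet(pd.DataFrame({
        "chrom": np.array(chrom_names, dtype=object)[chrom_idx],
        "start": start,
        "end": start + lengths,
    }))


# --------------------------------------------------------------------------
# planted signal model

def _signal_for_enrichment(target_e: float, local_bg: float) -> float:
    """Expected signal fragments giving log2((bg+s+1)/(bg+1)) = target_e."""
    return (local_bg + 1.0) * (2.0 ** target_e - 1.0)


def _raise_enrichment(sig: float, local_bg: float, delta: float) -> float:
    """Signal whose expected enrichment exceeds that of ``sig`` by delta."""
    return (local_bg + sig + 1.0) * (2.0 ** delta) - local_bg - 1.0


def _planted_signals(
    enh: pd.DataFrame, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Expected signal fragments (control, treated) per planted enhancer."""
    bg = cfg.background_rate / 2000.0 * (
        enh["end"].to_numpy() - enh["start"].to_numpy() + cfg.fragment_length - 1
    )
    base = cfg.signal_rate
    low = np.array([_signal_for_enrichment(cfg.de_novo_low_enrichment, b) for b in bg])
    up_hi = np.array([_raise_enrichment(base, b, cfg.effect_size) for b in bg])
    dn_hi = np.array(
        [_raise_enrichment(low[i], b, cfg.effect_size) for i, b in enumerate(bg)]
    )
    cluster_base = cfg.cluster_signal_mult * base
    sig_c = np.zeros(len(enh))
    sig_t = np.zeros(len(enh))
    cls = enh["class"].to_numpy()
    for i, c in enumerate(cls):
        if c == "unaffected":
            sig_c[i] = sig_t[i] = base
        elif c == "up":
            sig_c[i], sig_t[i] = base, up_hi[i]
        elif c == "down":
            sig_c[i], sig_t[i] = up_hi[i], base
        elif c == "de_novo_gained":
            sig_c[i], sig_t[i] = low[i], dn_hi[i]
        elif c == "de_novo_lost":
            sig_c[i], sig_t[i] = dn_hi[i], low[i]
        elif c == "cluster_gained":
            sig_c[i], sig_t[i] = cluster_base, cfg.se_signal_ratio * cluster_base
        elif c == "cluster_lost":
            sig_c[i], sig_t[i] = cfg.se_signal_ratio * cluster_base, cluster_base
        elif c == "cluster_unchanged":
            sig_c[i] = sig_t[i] = cluster_base
        elif c == "decoy":
            sig_c[i] = sig_t[i] = base
        else:  # pragma: no cover
            raise ValueError(f"unknown planted class {c!r}")
    return sig_c, sig_t


def _draw_counts(
    expected: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    expected = np.maximum(np.asarray(expected, dtype=float), 0.0)
    if cfg.count_noise == "poisson":
        return rng.poisson(expected)
    shape = 1.0 / cfg.nb_dispersion
    lam = np.where(
        expected > 0, rng.gamma(shape, 1.0 / shape, size=len(expected)) * expected, 0.0
    )
    return rng.poisson(lam)


def _signal_fragments(
    regions: pd.DataFrame,
    expected: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genome: GenomeLayout,
) -> pd.DataFrame:
    """Fragments guaranteed to overlap their source region by >= 1 bp."""
    n = _draw_counts(expected, cfg, rng)
    total = int(n.sum())
    if total == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    idx = np.repeat(np.arange(len(regions)), n)
    starts = regions["start"].to_numpy()[idx]
    ends = regions["end"].to_numpy()[idx]
    chroms = regions["chrom"].to_numpy()[idx]
    lo = np.maximum(starts - cfg.fragment_length + 1, 0)
    hi = ends  # exclusive upper bound for the fragment start
    frag_start = lo + (rng.random(total) * (hi - lo)).astype(np.int64)
    frag_end = frag_start + cfg.fragment_length
    lengths = np.array([genome.chrom_lengths[c] for c in chroms])
    frag_end = np.minimum(frag_end, lengths)
    frag_start = np.minimum(frag_start, frag_end - 1)
    return pd.DataFrame({"chrom": chroms, "start": frag_start, "end": frag_end})


def _background_fragments(
    cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    density = cfg.background_rate / 2000.0
    frames = []
    for chrom, length in cfg.genome.chrom_lengths.items():
        n = rng.poisson(density * length)
        start = np.sort(rng.integers(0, max(1, length - cfg.fragment_length),
                                     size=n))
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": start,
            "end": start + cfg.fragment_length,
        }))
    return pd.concat(frames, ignore_index=True)


def _jitter_peaks(
    regions: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator,
    widen: int = 0,
) -> pd.DataFrame:
    j = cfg.peak_jitter
    n = len(regions)
    start = regions["start"].to_numpy() - widen - rng.integers(0, j + 1, size=n)
    end = regions["end"].to_numpy() + widen + rng.integers(0, j + 1, size=n)
    lengths = np.array(
        [cfg.genome.chrom_lengths[c] for c in regions["chrom"]], dtype=np.int64
    )
    return pd.DataFrame({
        "chrom": regions["chrom"].to_numpy(),
        "start": np.maximum(start, 0),
        "end": np.minimum(end, lengths),
    })


# --------------------------------------------------------------------------

def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate the full synthetic experiment; see the module docstring."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    placer = _Placer(cfg.genome, rng)

    enh_classes = _alloc_counts(cfg.n_enhancers, cfg.class_fractions, rng)
    se_classes = _alloc_counts(cfg.n_se_clusters, cfg.se_class_fractions, rng)
    diff_like = {"up", "down", "de_novo_gained", "de_novo_lost"}

    n_linked = min(cfg.n_genes, cfg.n_se_clusters + cfg.n_enhancers)

    # average extra slack per slot, to spread elements over the genome
    gene_zone = 55_000  # room for a linked gene: offset up to 40 kb + span
    n_slots = (
        cfg.n_enhancers + cfg.n_se_clusters + cfg.n_decoys
        + cfg.n_spurious_peaks + max(cfg.n_genes - n_linked, 0)
    )
    width_guess = (
        cfg.n_enhancers * (cfg.enhancer_length[1] + gene_zone)
        + cfg.n_se_clusters * (cfg.enhancers_per_cluster * 11_000 + gene_zone)
        + (cfg.n_decoys + cfg.n_spurious_peaks) * cfg.enhancer_length[1]
        + max(cfg.n_genes - n_linked, 0) * 12_000
    )
    free = cfg.genome.total_length - width_guess - (n_slots + 1) * SLOT_BUFFER
    if free < 0:
        raise ValueError(
            "genome too small to place the requested elements without "
            "violating the required spacing"
        )
    extra_gap = int(free / max(n_slots, 1))

    enh_rows: list[dict] = []
    cluster_rows: list[dict] = []
    gene_slots: list[dict] = []  # pending gene placements

    def _enh_len() -> int:
        return int(rng.integers(cfg.enhancer_length[0], cfg.enhancer_length[1] + 1))

    # singleton enhancers (linked genes live in the same slot, downstream);
    # links go to differential enhancers first, then unaffected ones, so
    # both contrasting gene groups exist
    link_flags = np.zeros(cfg.n_enhancers, dtype=bool)
    diff_idx = np.flatnonzero(np.isin(enh_classes, list(diff_like)))
    other_idx = np.flatnonzero(~np.isin(enh_classes, list(diff_like)))
    n_single_links = max(n_linked - cfg.n_se_clusters, 0)
    if n_single_links:
        order = np.concatenate(
            [rng.permutation(diff_idx), rng.permutation(other_idx)])
        link_flags[order[:n_single_links].astype(int)] = True
    expr_class_of = {
        "up": "up", "de_novo_gained": "up",
        "down": "down", "de_novo_lost": "down",
        "unaffected": "neutral",
    }
    for i in range(cfg.n_enhancers):
        length = _enh_len()
        width = length + (gene_zone if link_flags[i] else 0)
        chrom, pos = placer.place(width, extra_gap)
        enh_rows.append({
            "chrom": chrom, "start": pos, "end": pos + length,
            "class": enh_classes[i], "cluster_id": -1, "linked_gene": "",
        })
        if link_flags[i]:
            gene_slots.append({
                "chrom": chrom, "anchor_end": pos + length,
                "region": f"enh_{i}", "enh_idx": i,
                "expr_class": expr_class_of[enh_classes[i]],
            })

    # SE clusters: constituents within the stitching distance of a neighbor
    for k in range(cfg.n_se_clusters):
        lengths = [_enh_len() for _ in range(cfg.enhancers_per_cluster)]
        gaps = [int(rng.integers(2000, 8001))
                for _ in range(cfg.enhancers_per_cluster - 1)]
        span = sum(lengths) + sum(gaps)
        chrom, pos = placer.place(span + gene_zone, extra_gap)
        cur = pos
        first_idx = len(enh_rows)
        for j, length in enumerate(lengths):
            enh_rows.append({
                "chrom": chrom, "start": cur, "end": cur + length,
                "class": f"cluster_{se_classes[k]}", "cluster_id": k,
                "linked_gene": "",
            })
            cur += length + (gaps[j] if j < len(gaps) else 0)
        cluster_rows.append({
            "cluster_id": k, "chrom": chrom, "start": pos,
            "end": enh_rows[-1]["end"], "se_class": se_classes[k],
        })
        if len(gene_slots) < n_linked:
            gene_slots.append({
                "chrom": chrom, "anchor_end": enh_rows[-1]["end"],
                "region": f"cluster_{k}", "enh_idx": first_idx,
                "expr_class": "up" if se_classes[k] == "gained"
                else ("down" if se_classes[k] == "lost" else "neutral"),
            })

    # decoy co-occupied regions: removable only by the exclusion filters
    decoy_rows = []
    for i in range(cfg.n_decoys):
        length = _enh_len()
        chrom, pos = placer.place(length + 12_000, extra_gap)
        kind = "k4me3" if i % 2 == 0 else "promoter"
        decoy_rows.append({
            "chrom": chrom, "start": pos, "end": pos + length,
            "class": "decoy", "kind": kind,
        })

    enh = pd.DataFrame(
        enh_rows,
        columns=["chrom", "start", "end", "class", "cluster_id", "linked_gene"],
    )
    decoys = pd.DataFrame(
        decoy_rows, columns=["chrom", "start", "end", "class", "kind"])
    clusters = pd.DataFrame(
        cluster_rows, columns=["cluster_id", "chrom", "start", "end", "se_class"])

    # genes: linked genes downstream of their region, the rest in own slots
    genes: list[GeneModel] = []
    gene_rows = []

    def _make_gene(gene_id: str, chrom: str, tss: int, strand: str,
                   rng: np.random.Generator) -> GeneModel:
        n_exons = int(rng.integers(2, 4))
        pos = tss
        starts, ends = [], []
        for e in range(n_exons):
            exon_len = int(rng.integers(300, 1500))
            starts.append(pos)
            ends.append(pos + exon_len)
            pos += exon_len + int(rng.integers(500, 3000))
        exons = IntervalSet(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends}))
        return GeneModel(gene_id, chrom, strand, tss, exons)

    for g, slot in enumerate(gene_slots):
        offset = int(rng.integers(5000, 40_001))
        gid = f"gene_{g:04d}"
        gene = _make_gene(gid, slot["chrom"], slot["anchor_end"] + offset, "+", rng)
        genes.append(gene)
        gene_rows.append({
            "gene_id": gid, "expr_class": slot["expr_class"],
            "linked_region": slot["region"],
        })
        enh.loc[slot["enh_idx"], "linked_gene"] = gid
    for g in range(len(gene_slots), cfg.n_genes):
        chrom, pos = placer.place(12_000, extra_gap)
        gid = f"gene_{g:04d}"
        if rng.random() < 0.5:
            genes.append(_make_gene(gid, chrom, pos + 1000, "+", rng))
        else:
            genes.append(_reverse_gene(gid, chrom, pos, rng))
        gene_rows.append({
            "gene_id": gid, "expr_class": "neutral", "linked_region": "",
        })
    gene_truth = pd.DataFrame(
        gene_rows, columns=["gene_id", "expr_class", "linked_region"])

    # move promoter decoys onto gene promoter windows (if any genes exist)
    if len(genes):
        promoter_targets = rng.integers(0, len(genes), size=len(decoys))
        for i in decoys.index[decoys["kind"] == "promoter"]:
            g = genes[int(promoter_targets[i])]
            length = int(decoys.loc[i, "end"] - decoys.loc[i, "start"])
            start = max(0, g.tss - length // 2)
            decoys.loc[i, ["chrom", "start", "end"]] = [
                g.chrom, start, start + length]

    # spurious single-sample peaks
    spur_rows = []
    for _ in range(cfg.n_spurious_peaks):
        length = _enh_len()
        chrom, pos = placer.place(length, extra_gap)
        spur_rows.append({"chrom": chrom, "start": pos, "end": pos + length})
    spurious = pd.DataFrame(spur_rows, columns=["chrom", "start", "end"])

    # ------------------------------------------------------------------
    # peak sets
    planted = pd.concat(
        [enh[["chrom", "start", "end", "class"]],
         decoys[["chrom", "start", "end", "class"]]],
        ignore_index=True,
    )
    active_ctrl = ~planted["class"].isin(["de_novo_gained"])
    active_trt = ~planted["class"].isin(["de_novo_lost"])

    def _ac_peaks(active: np.ndarray) -> pd.DataFrame:
        return _jitter_peaks(planted[np.asarray(active)], cfg, rng)

    ac_peaks = {
        ("control", 1): _ac_peaks(active_ctrl),
        ("control", 2): _ac_peaks(active_ctrl),
        ("treated", 1): _ac_peaks(active_trt),
        ("treated", 2): _ac_peaks(active_trt),
    }
    # one spurious peak per random H3K27ac sample
    sample_keys = list(ac_peaks)
    spur_assign = rng.integers(0, len(sample_keys), size=len(spurious))
    for s, key in enumerate(sample_keys):
        extra = spurious[spur_assign == s]
        if len(extra):
            ac_peaks[key] = pd.concat(
                [ac_peaks[key], _jitter_peaks(extra, cfg, rng)],
                ignore_index=True)

    me1_peaks = {
        key: _jitter_peaks(planted, cfg, rng, widen=500) for key in sample_keys
    }
    k4me3_src = decoys[decoys["kind"] == "k4me3"][["chrom", "start", "end"]]
    prom_rows = pd.DataFrame({
        "chrom": [g.chrom for g in genes],
        "start": [max(0, g.tss - 500) for g in genes],
        "end": [g.tss + 500 for g in genes],
    })
    k4me3_peaks = pd.concat([k4me3_src, prom_rows], ignore_index=True)

    # ------------------------------------------------------------------
    # fragments
    sig_c, sig_t = _planted_signals(planted, cfg)
    signal_by_cond = {"control": sig_c, "treated": sig_t}

    tracks: list[SampleTrack] = []
    for cond in ("control", "treated"):
        short = "ctrl" if cond == "control" else "trt"
        for rep in (1, 2):
            # one input per ChIP replicate, so input noise enters the
            # within-group residual and the moderated t stays calibrated
            tracks.append(SampleTrack(
                sample_id=f"input_{short}_r{rep}", mark="input",
                condition=cond, replicate=rep, peaks=None,
                fragments=IntervalSet(_background_fragments(cfg, rng)),
            ))
            frags = pd.concat([
                _background_fragments(cfg, rng),
                _signal_fragments(planted, signal_by_cond[cond], cfg, rng,
                                  cfg.genome),
            ], ignore_index=True)
            tracks.append(SampleTrack(
                sample_id=f"H3K27ac_{short}_r{rep}", mark="H3K27ac",
                condition=cond, replicate=rep,
                peaks=IntervalSet(ac_peaks[(cond, rep)]),
                fragments=IntervalSet(frags),
            ))
            if cfg.simulate_brd4:
                bfrags = pd.concat([
                    _background_fragments(cfg, rng),
                    _signal_fragments(planted, signal_by_cond[cond], cfg, rng,
                                      cfg.genome),
                ], ignore_index=True)
                active = active_ctrl if cond == "control" else active_trt
                tracks.append(SampleTrack(
                    sample_id=f"BRD4_{short}_r{rep}", mark="BRD4",
                    condition=cond, replicate=rep,
                    peaks=IntervalSet(_jitter_peaks(
                        planted[np.asarray(active)], cfg, rng)),
                    fragments=IntervalSet(bfrags),
                ))
    for cond, rep in sample_keys:
        short = "ctrl" if cond == "control" else "trt"
        tracks.append(SampleTrack(
            sample_id=f"H3K4me1_{short}_r{rep}", mark="H3K4me1",
            condition=cond, replicate=rep,
            peaks=IntervalSet(me1_peaks[(cond, rep)]), fragments=None,
            library_size=None,
        ))
    tracks.append(SampleTrack(
        sample_id="H3K4me3_ctrl_r1", mark="H3K4me3", condition="control",
        replicate=1, peaks=IntervalSet(k4me3_peaks), fragments=None,
    ))

    # ------------------------------------------------------------------
    # expression
    expr_rows = []
    for gene, row in zip(genes, gene_truth.itertuples()):
        baseline = float(rng.lognormal(np.log(cfg.expr_baseline_mean), 1.0))
        delta = {"up": cfg.expr_effect, "down": -cfg.expr_effect}.get(
            row.expr_class, 0.0)
        mu_c = baseline
        mu_t = baseline * 2.0 ** delta
        shape = 1.0 / cfg.expr_dispersion
        lam_c = rng.gamma(shape, mu_c / shape)
        lam_t = rng.gamma(shape, mu_t / shape)
        expr_rows.append({
            "gene_id": gene.gene_id, "length": gene.gene_length,
            "count_ctrl": int(rng.poisson(lam_c)),
            "count_trt": int(rng.poisson(lam_t)),
        })
    expression = pd.DataFrame(
        expr_rows, columns=["gene_id", "length", "count_ctrl", "count_trt"])

    # ------------------------------------------------------------------
    # lncRNAs
    n_planted = int(round(cfg.n_lncrnas * cfg.lncrna_overlap_fraction))
    n_planted = min(n_planted, len(enh))
    lnc_rows = []
    if n_planted:
        targets = rng.choice(len(enh), size=n_planted, replace=False)
        for i, t in enumerate(targets):
            r = enh.iloc[int(t)]
            length = int(rng.integers(cfg.lncrna_length[0],
                                      cfg.lncrna_length[1] + 1))
            lo = max(0, int(r["start"]) - length + 1)
            hi = int(r["end"]) - 1
            start = int(rng.integers(lo, hi + 1))
            end = min(start + length, cfg.genome.chrom_lengths[r["chrom"]])
            lnc_rows.append({
                "lnc_id": f"lnc_{i:04d}", "chrom": r["chrom"],
                "start": start, "end": end, "planted_enhancer": int(t),
            })
    n_free = cfg.n_lncrnas - n_planted
    if n_free > 0:
        lengths = rng.integers(cfg.lncrna_length[0], cfg.lncrna_length[1] + 1,
                               size=n_free)
        placed = place_random_intervals(lengths, cfg.genome, rng)
        for i, iv in enumerate(placed):
            lnc_rows.append({
                "lnc_id": f"lnc_{n_planted + i:04d}", "chrom": iv.chrom,
                "start": iv.start, "end": iv.end, "planted_enhancer": -1,
            })
    lnc_truth = pd.DataFrame(
        lnc_rows, columns=["lnc_id", "chrom", "start", "end", "planted_enhancer"])
    lncrnas = IntervalSet(lnc_truth[["chrom", "start", "end"]].copy()) \
        if len(lnc_truth) else IntervalSet()

    truth = TruthTable(
        enhancers=enh, clusters=clusters, genes=gene_truth, lncrnas=lnc_truth)
    return SimulatedExperiment(
        genome=cfg.genome, tracks=tracks, genes=genes, expression=expression,
        lncrnas=lncrnas, truth=truth, config=cfg,
    )


def _reverse_gene(gene_id: str, chrom: str, pos: int,
                  rng: np.random.Generator) -> GeneModel:
    """Minus-strand gene laid out leftward from its TSS."""
    tss = pos + 11_000
    n_exons = int(rng.integers(2, 4))
    cur = tss
    starts, ends = [], []
    for _ in range(n_exons):
        exon_len = int(rng.integers(300, 1500))
        starts.append(cur - exon_len)
        ends.append(cur)
        cur -= exon_len + int(rng.integers(500, 3000))
    exons = IntervalSet(pd.DataFrame(
        {"chrom": chrom, "start": sorted(starts), "end": sorted(ends)}))
    return GeneModel(gene_id, chrom, "-", tss - 1, exons)


def simulate_null_overlap(config: SimulationConfig) -> IntervalSet:
    """lncRNAs placed uniformly, independent of any enhancer."""
    rng = np.random.default_rng(config.seed)
    lengths = rng.integers(
        config.lncrna_length[0], config.lncrna_length[1] + 1,
        size=config.n_lncrnas,
    )
    return place_random_intervals(lengths, config.genome, rng)
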