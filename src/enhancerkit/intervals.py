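"""Genomic interval algebra and per-region fragment counting.

All coordinates are 0-based half-open (BED convention). Overlap means at
least one shared base, so abutting intervals (``a.end == b.start``) do not
overlap; merging, however, is a coverage union and therefore joins touching
intervals. Strand is carried through but ignored by all region arithmetic —
histone-mark and fragment data are unstranded; strand only matters for gene
TSS determination in :class:`GeneModel`.

The heavy operations (merge, overlap counting, membership against a merged
set) are vectorized on per-chromosome sorted numpy arrays. For disjoint
sorted query intervals the number of intervals of a set overlapping a window
[s, e) equals ``#{start < e} - #{end <= s}``, which two ``searchsorted``
calls compute in O(log n) per window.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GenomeLayout",
    "IntervalSet",
    "SampleTrack",
    "GeneModel",
    "merge_intervals",
    "count_support",
    "scaled_region_counts",
    "genomic_distribution",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
]


class SchemaError(ValueError):
    """A text input violates the expected tabular schema."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths of the reference the intervals live on."""

    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("genome needs at least one chromosome")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.chrom_lengths.items():
                fh.write(f"{chrom}\t{length}\n")


_CORE_COLS = ["chrom", "start", "end"]


class IntervalSet:
    """An ordered collection of genomic intervals backed by a DataFrame.

    Extra columns (name, score, ...) are carried through sorting and
    subsetting but dropped by :meth:`merge`.
    """

    def __init__(self, data=None, genome: GenomeLayout | None = None):
        if data is None:
            df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                               zip(_CORE_COLS, [str, np.int64, np.int64])})
        elif isinstance(data, pd.DataFrame):
            df = data.copy()
        elif isinstance(data, IntervalSet):
            df = data.df.copy()
        else:
            rows = list(data)
            if rows and isinstance(rows[0], GenomicInterval):
                df = pd.DataFrame(
                    {
                        "chrom": [iv.chrom for iv in rows],
                        "start": [iv.start for iv in rows],
                        "end": [iv.end for iv in rows],
                        "strand": [iv.strand for iv in rows],
                    }
                )
            else:
                df = pd.DataFrame(rows, columns=_CORE_COLS[: len(rows[0]) if rows else 3])
        missing = [c for c in _CORE_COLS if c not in df.columns]
        if missing:
            raise SchemaError(f"interval table lacks columns {missing}")
        df = df.reset_index(drop=True)
        if len(df):
            df["chrom"] = df["chrom"].astype(str)
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            bad = (df["start"] < 0) | (df["start"] >= df["end"])
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                r = df.iloc[i]
                raise ValueError(
                    f"invalid interval {r.chrom}:{r.start}-{r.end} at row {i}"
                )
        self.df = df
        self.genome = genome
        if genome is not None:
            self.validate_bounds()

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        strands = (
            self.df["strand"] if "strand" in self.df.columns
            else itertools.repeat(".")
        )
        for chrom, start, end, strand in zip(
            self.df["chrom"], self.df["start"], self.df["end"], strands
        ):
            yield GenomicInterval(chrom, int(start), int(end), strand)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self.df[_CORE_COLS].reset_index(drop=True)
        b = other.df[_CORE_COLS].reset_index(drop=True)
        return a.equals(b)

    @property
    def starts(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_bases(self) -> int:
        """Covered bases of the merged set."""
        m = self.merge()
        return int(m.lengths.sum())

    def validate_bounds(self) -> None:
        if self.genome is None or not len(self):
            return
        lengths = self.df["chrom"].map(self.genome.chrom_lengths)
        if lengths.isna().any():
            r = self.df[lengths.isna()].iloc[0]
            raise ValueError(
                f"interval {r.chrom}:{r.start}-{r.end} on unknown chromosome"
            )
        over = self.df["end"] > lengths
        if over.any():
            r = self.df[over].iloc[0]
            raise ValueError(
                f"interval {r.chrom}:{r.start}-{r.end} exceeds chromosome bounds"
            )

    # -- algebra -----------------------------------------------------------
    def sort(self) -> "IntervalSet":
        out = IntervalSet(
            self.df.sort_values(["chrom", "start", "end"], kind="mergesort"),
            genome=None,
        )
        out.genome = self.genome
        return out

    def merge(self) -> "IntervalSet":
        """Coverage union: sorted, pairwise disjoint; touching intervals join."""
        if not len(self):
            return IntervalSet(genome=self.genome)
        self.validate_bounds()
        parts = []
        for chrom, sub in self.df.groupby("chrom", sort=True):
            starts = np.sort(sub["start"].to_numpy())
            order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
            ends = sub["end"].to_numpy()[order]
            run_end = np.maximum.accumulate(ends)
            # a new block starts where the interval begins strictly after
            # the running coverage end (end == start still merges)
            new_block = np.empty(len(starts), dtype=bool)
            new_block[0] = True
            new_block[1:] = starts[1:] > run_end[:-1]
            block = np.cumsum(new_block) - 1
            mstarts = starts[new_block]
            mends = np.zeros(block[-1] + 1, dtype=np.int64)
            np.maximum.at(mends, block, ends)
            mends = np.maximum.accumulate(mends)  # guard; maximum.at suffices
            parts.append(pd.DataFrame({"chrom": chrom, "start": mstarts, "end": mends}))
        out = IntervalSet(pd.concat(parts, ignore_index=True))
        out.genome = self.genome
        return out

    def _per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        return out

    def count_overlaps(self, other: "IntervalSet") -> np.ndarray:
        """Number of intervals of ``other`` overlapping each interval of self.

        Each interval of ``other`` is counted once per region it overlaps by
        at least one base (per-region independence).
        """
        counts = np.zeros(len(self), dtype=np.int64)
        if not len(other):
            return counts
        by_chrom = {}
        for chrom, sub in other.df.groupby("chrom", sort=False):
            by_chrom[chrom] = (
                np.sort(sub["start"].to_numpy()),
                np.sort(sub["end"].to_numpy()),
            )
        chroms = self.chroms
        starts, ends = self.starts, self.ends
        for chrom, (ost, oen) in by_chrom.items():
            mask = chroms == chrom
            if not mask.any():
                continue
            n_start = np.searchsorted(ost, ends[mask], side="left")
            n_end = np.searchsorted(oen, starts[mask], side="right")
            counts[mask] = n_start - n_end
        return counts

    def overlaps_any(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per interval of self: overlaps >=1 base of ``other``."""
        flags = np.zeros(len(self), dtype=bool)
        if not len(other) or not len(self):
            return flags
        merged = other.merge()
        chroms = self.chroms
        starts, ends = self.starts, self.ends
        for chrom, (mst, men) in merged._per_chrom().items():
            mask = chroms == chrom
            if not mask.any():
                continue
            idx = np.searchsorted(men, starts[mask], side="right")
            ok = idx < len(mst)
            hit = np.zeros(mask.sum(), dtype=bool)
            hit[ok] = mst[idx[ok]] < ends[mask][ok]
            flags[mask] = hit
        return flags

    def subset(self, mask) -> "IntervalSet":
        out = IntervalSet(self.df[np.asarray(mask)].reset_index(drop=True))
        out.genome = self.genome
        return out

    @classmethod
    def concat(cls, sets: Iterable["IntervalSet"]) -> "IntervalSet":
        sets = list(sets)
        frames = [s.df[_CORE_COLS] for s in sets if len(s)]
        genome = next((s.genome for s in sets if s.genome is not None), None)
        if not frames:
            return cls(genome=genome)
        out = cls(pd.concat(frames, ignore_index=True))
        out.genome = genome
        return out


def merge_intervals(intervals: IntervalSet) -> IntervalSet:
    """Merge overlapping and touching intervals into a disjoint sorted set."""
    return intervals.merge()


def count_support(
    merged: IntervalSet, per_sample_peaks: Sequence[IntervalSet]
) -> np.ndarray:
    """Per merged region, the number of samples with >=1 bp peak overlap."""
    support = np.zeros(len(merged), dtype=np.int64)
    for peaks in per_sample_peaks:
        support += merged.overlaps_any(peaks).astype(np.int64)
    return support


@dataclass
class SampleTrack:
    """One sequencing sample: its peak calls and/or fragment placements."""

    sample_id: str
    mark: str  # H3K27ac, H3K4me1, H3K4me3, BRD4, input
    condition: str  # control / treated
    replicate: int = 1
    peaks: IntervalSet | None = None
    fragments: IntervalSet | None = None
    library_size: int | None = None

    def __post_init__(self) -> None:
        if self.fragments is not None:
            if self.library_size is None:
                self.library_size = len(self.fragments)
            if self.library_size <= 0:
                raise ValueError(
                    f"sample {self.sample_id}: library_size must be > 0"
                )


def scaled_region_counts(regions: IntervalSet, track: SampleTrack) -> np.ndarray:
    """Fragments overlapping each region, scaled to 1 million total fragments.

    A fragment counts once per region it overlaps by >=1 bp; a paired-end
    fragment is one interval (the pair counts once).
    """
    if track.fragments is None:
        raise ValueError(f"sample {track.sample_id} has no fragments")
    if track.library_size is None or track.library_size <= 0:
        raise ValueError(f"sample {track.sample_id}: library_size must be > 0")
    raw = regions.count_overlaps(track.fragments)
    return raw * (1e6 / track.library_size)


@dataclass
class GeneModel:
    """A gene: TSS (strand-aware), exon structure and exonic length."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: IntervalSet
    gene_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.gene_length is None:
            self.gene_length = self.exons.total_bases
        if self.gene_length <= 0:
            raise ValueError(f"gene {self.gene_id}: gene_length must be > 0")

    @property
    def span(self) -> GenomicInterval:
        lo = min(int(self.exons.starts.min()), self.tss)
        hi = max(int(self.exons.ends.max()), self.tss + 1)
        return GenomicInterval(self.chrom, lo, hi, self.strand)


def promoter_windows(
    genes: Sequence[GeneModel], flank: int = 1000,
    genome: GenomeLayout | None = None,
) -> IntervalSet:
    """TSS +- flank windows, clipped at zero (and chromosome ends if known)."""
    rows = []
    for g in genes:
        start = max(0, g.tss - flank)
        end = g.tss + flank
        if genome is not None:
            end = min(end, genome.chrom_lengths.get(g.chrom, end))
        rows.append((g.chrom, start, end))
    return IntervalSet(pd.DataFrame(rows, columns=_CORE_COLS))


def exon_union(genes: Sequence[GeneModel]) -> IntervalSet:
    return IntervalSet.concat([g.exons for g in genes]).merge()


def gene_spans(genes: Sequence[GeneModel]) -> IntervalSet:
    rows = [(g.span.chrom, g.span.start, g.span.end) for g in genes]
    return IntervalSet(pd.DataFrame(rows, columns=_CORE_COLS))


def genomic_distribution(
    regions: IntervalSet,
    genes: Sequence[GeneModel],
    promoter_flank: int = 1000,
) -> pd.Series:
    """Fraction of regions per category, priority promoter > exon > intron.

    A region overlapping a TSS+-flank window is a promoter region; otherwise
    exon if it touches any exonic base; otherwise intron if inside a gene
    span; otherwise intergenic. Fractions sum to 1 over non-empty input.
    """
    cats = ["promoter", "exon", "intron", "intergenic"]
    if not len(regions):
        return pd.Series(dtype=float, name="fraction")
    labels = classify_regions(regions, genes, promoter_flank)
    frac = labels.value_counts(normalize=True).reindex(cats, fill_value=0.0)
    frac.name = "fraction"
    return frac


def classify_regions(
    regions: IntervalSet,
    genes: Sequence[GeneModel],
    promoter_flank: int = 1000,
) -> pd.Series:
    """Per-region category label; see :func:`genomic_distribution`."""
    prom = regions.overlaps_any(promoter_windows(genes, promoter_flank))
    exon = regions.overlaps_any(exon_union(genes))
    body = regions.overlaps_any(gene_spans(genes))
    labels = np.where(prom, "promoter",
                      np.where(exon, "exon",
                               np.where(body, "intron", "intergenic")))
    return pd.Series(labels, name="category")


# -- I/O -------------------------------------------------------------------

def read_bed(path, genome: GenomeLayout | None = None) -> IntervalSet:
    """Read BED3/BED6 (tab-separated, no header). Raises SchemaError with the
    1-based line number of the first malformed line."""
    # fast path: well-formed files parse vectorized; any failure falls back
    # to the line scanner below for a precise diagnostic
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
            dtype={0: str, 1: np.int64, 2: np.int64},
        )
        if len(df) and ((df["start"] < 0) | (df["start"] >= df["end"])).any():
            raise ValueError
        return IntervalSet(df, genome=genome)
    except SchemaError:
        raise
    except Exception:
        pass
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}: line {lineno}: expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise SchemaError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if not (0 <= start < end):
                raise SchemaError(
                    f"{path}: line {lineno}: invalid coordinates {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((fields[0], start, end, name, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return IntervalSet(df, genome=genome)


def write_bed(intervals: IntervalSet, path, extra_cols: Sequence[str] = ()) -> None:
    """Write BED3 (+ optional extra columns, tab-separated, no header)."""
    cols = list(_CORE_COLS) + [c for c in extra_cols if c in intervals.df.columns]
    intervals.df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gene_table(path) -> list[GeneModel]:
    """Gene annotation TSV: gene_id, chrom, strand, tss, exon_starts,
    exon_ends (comma-separated), gene_length."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chrom", "strand", "tss", "exon_starts", "exon_ends"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"{path}: gene table needs columns {sorted(required)}"
        )
    genes = []
    for _, r in df.iterrows():
        starts = [int(x) for x in str(r.exon_starts).split(",") if x]
        ends = [int(x) for x in str(r.exon_ends).split(",") if x]
        if len(starts) != len(ends):
            raise SchemaError(f"{path}: gene {r.gene_id}: exon list mismatch")
        exons = IntervalSet(pd.DataFrame(
            {"chrom": r.chrom, "start": starts, "end": ends}))
        length = int(r.gene_length) if "gene_length" in df.columns else None
        genes.append(GeneModel(str(r.gene_id), str(r.chrom), str(r.strand),
                               int(r.tss), exons, length))
    return genes


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
            "tss": g.tss,
            "exon_starts": ",".join(map(str, g.exons.starts)),
            "exon_ends": ",".join(map(str, g.exons.ends)),
            "gene_length": g.gene_length,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
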