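"""Binned signal tracks, gene annotations, and TSS-centered feature windows.

Coordinate conventions used package-wide:

* all genomic coordinates are 0-based, half-open (bedGraph/BED native);
* tracks are stored as one fixed-width bin vector per chromosome, where
  bin ``k`` covers ``[k*bin_size, (k+1)*bin_size)``;
* the TSS bin of a gene is ``tss // bin_size``;
* feature windows have an odd number of bins ``W = context//bin_size + 1``
  so the TSS bin sits exactly in the middle, and minus-strand windows are
  reversed so that increasing bin index always means downstream of the TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPERIMENTAL = "experimental"
IMPUTED = "imputed"


class TrackError(ValueError):
    """Malformed or inconsistent track/annotation input."""


@dataclass
class BinnedTrack:
    """One genome-wide signal vector per chromosome at fixed bin size.

    Values are nonnegative: −log10(p) signal for histone PTM tracks, read
    coverage for MNase tracks.
    """

    cell_type: str
    assay: str
    bin_size: int
    data: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: str = EXPERIMENTAL

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise TrackError(f"bin_size must be positive, got {self.bin_size}")
        if self.provenance not in (EXPERIMENTAL, IMPUTED):
            raise TrackError(f"unknown provenance {self.provenance!r}")
        for chrom, v in self.data.items():
            v = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(v)):
                raise TrackError(f"non-finite values on {chrom}")
            if np.any(v < 0):
                raise TrackError(f"negative values on {chrom}")
            self.data[chrom] = v

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def n_bins(self) -> int:
        return int(sum(v.size for v in self.data.values()))

    def values_concat(self) -> np.ndarray:
        """All bin values concatenated in chromosome order."""
        if not self.data:
            return np.empty(0)
        return np.concatenate([self.data[c] for c in self.data])

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            cell_type=self.cell_type,
            assay=self.assay,
            bin_size=self.bin_size,
            data={c: v.copy() for c, v in self.data.items()},
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise TrackError(f"{self.gene_id}: negative TSS")
        if self.strand not in ("+", "-"):
            raise TrackError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class FeatureWindow:
    """TSS-centered, strand-oriented signal matrix for one gene.

    ``E`` has shape (W, A): W bins (odd, TSS central, index increases
    downstream) by A assays in the fixed ``assays`` order.
    """

    gene_id: str
    cell_type: str
    E: np.ndarray
    assays: list[str]
    bin_size: int

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.ndim != 2 or self.E.shape[1] != len(self.assays):
            raise TrackError("E must be (W, n_assays)")
        if self.E.shape[0] % 2 == 0:
            raise TrackError("W must be odd so the TSS bin is central")

    @property
    def W(self) -> int:
        return self.E.shape[0]

    @property
    def tss_index(self) -> int:
        return self.W // 2

    def assay_column(self, assay: str) -> np.ndarray:
        try:
            return self.E[:, self.assays.index(assay)]
        except ValueError:
            raise TrackError(f"assay {assay!r} not in window") from None

    def copy(self) -> "FeatureWindow":
        return FeatureWindow(self.gene_id, self.cell_type, self.E.copy(),
                             list(self.assays), self.bin_size)


# ---------------------------------------------------------------------------
# bedGraph / BED / expression I/O
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, bin_size: int, *, cell_type: str = "",
                  assay: str = "", provenance: str = EXPERIMENTAL,
                  chrom_sizes: Mapping[str, int] | None = None) -> BinnedTrack:
    """Read a bedGraph file into fixed-size bins.

    Interval values are averaged into bins with length weighting; bins not
    covered by any interval are 0.  ``chrom_sizes`` (bp) fixes the vector
    lengths; otherwise each chromosome extends to its last covered interval.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise TrackError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise TrackError(f"{path}:{lineno}: non-numeric start/end/value") from None
            if end <= start:
                raise TrackError(f"{path}:{lineno}: empty or inverted interval")
            if value < 0:
                raise TrackError(f"{path}:{lineno}: negative value {value}")
            rows.append((parts[0], start, end, value))

    track = BinnedTrack(cell_type=cell_type, assay=assay, bin_size=bin_size,
                        provenance=provenance)
    if not rows and not chrom_sizes:
        return track

    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, s, e, v in rows:
        by_chrom.setdefault(chrom, []).append((s, e, v))

    chrom_names = list(chrom_sizes) if chrom_sizes else list(by_chrom)
    for chrom in chrom_names:
        ivals = by_chrom.get(chrom, [])
        if chrom_sizes:
            n = -(-chrom_sizes[chrom] // bin_size)
        else:
            n = -(-max(e for _, e, _ in ivals) // bin_size)
        wsum = np.zeros(n)
        for s, e, v in ivals:
            b0, b1 = s // bin_size, (e - 1) // bin_size
            if b0 == b1:
                wsum[b0] += (e - s) * v
            else:
                wsum[b0] += ((b0 + 1) * bin_size - s) * v
                wsum[b1] += (e - b1 * bin_size) * v
                if b1 > b0 + 1:
                    wsum[b0 + 1:b1] += bin_size * v
        track.data[chrom] = wsum / bin_size
    return track


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    """Write a binned track as bedGraph, merging runs of equal-valued bins."""
    with open(path, "w") as fh:
        for chrom, vals in track.data.items():
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vals.size]])
            bs = track.bin_size
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s * bs}\t{e * bs}\t{vals[s]:g}\n")


def read_bed6(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from BED6 (name = gene id, col 6 = strand).

    The thickStart-style TSS is taken as ``start`` for '+' genes and
    ``end - 1`` for '−' genes.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"])
    genes = []
    for row in df.itertuples(index=False):
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        genes.append(GeneAnnotation(str(row.name), str(row.chrom), tss, str(row.strand)))
    return genes


def write_bed6(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start = g.tss if g.strand == "+" else g.tss  # point feature at TSS
            end = start + 1
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_expression(path: str | Path,
                    genes: Sequence[GeneAnnotation] | None = None) -> pd.DataFrame:
    """Read a TPM table (TSV: gene_id + one numeric column per cell type).

    Zeros are valid; negative TPM and duplicated gene ids are errors.  When
    ``genes`` is given, table rows absent from the annotation are dropped
    with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        df = df.rename(columns={df.columns[0]: "gene_id"})
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise TrackError(f"duplicate gene_id in expression table: {dup.iloc[0]!r}")
    df = df.set_index("gene_id")
    vals = df.to_numpy(dtype=float)
    if np.any(vals < 0):
        bad = df.index[np.any(vals < 0, axis=1)][0]
        raise TrackError(f"negative TPM for gene {bad!r}")
    if genes is not None:
        known = {g.gene_id for g in genes}
        extra = [g for g in df.index if g not in known]
        if extra:
            logger.warning("dropping %d expression rows not in annotation (e.g. %s)",
                           len(extra), extra[0])
            df = df.drop(index=extra)
    return df


def write_expression(tpm: pd.DataFrame, path: str | Path) -> None:
    tpm.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def window_bins(context: int, bin_size: int) -> int:
    """Number of bins in a TSS-centered window: context/bin_size + 1 (odd)."""
    if context % bin_size != 0:
        raise TrackError(f"bin_size {bin_size} does not divide context {context}")
    w = context // bin_size + 1
    if w % 2 == 0:
        raise TrackError(f"context {context} at bin_size {bin_size} gives even W={w}")
    return w


def extract_vector(track: BinnedTrack, gene: GeneAnnotation, context: int) -> np.ndarray:
    """TSS-centered, strand-oriented bin vector of one track for one gene."""
    w = window_bins(context, track.bin_size)
    half = w // 2
    if gene.chrom not in track.data:
        raise TrackError(f"{gene.gene_id}: chromosome {gene.chrom} not in track")
    vals = track.data[gene.chrom]
    center = gene.tss // track.bin_size
    lo, hi = center - half, center + half + 1
    if lo < 0 or hi > vals.size:
        raise TrackError(
            f"{gene.gene_id}: window [{lo}, {hi}) exceeds {gene.chrom} "
            f"bounds (0, {vals.size})")
    win = vals[lo:hi].copy()
    if gene.strand == "-":
        win = win[::-1].copy()
    return win


def extract_window(tracks: Mapping[str, BinnedTrack], gene: GeneAnnotation,
                   context: int, *, assay_order: Sequence[str] | None = None,
                   cell_type: str | None = None) -> FeatureWindow:
    """Build the W × A feature matrix for one gene from per-assay tracks."""
    order = list(assay_order) if assay_order is not None else sorted(tracks)
    sizes = {tracks[a].bin_size for a in order}
    if len(sizes) != 1:
        raise TrackError(f"tracks disagree on bin_size: {sorted(sizes)}")
    cols = [extract_vector(tracks[a], gene, context) for a in order]
    ct = cell_type if cell_type is not None else tracks[order[0]].cell_type
    return FeatureWindow(gene.gene_id, ct, np.column_stack(cols), order,
                         bin_size=sizes.pop())


def windows_for_genes(tracks: Mapping[str, BinnedTrack],
                      genes: Iterable[GeneAnnotation], context: int,
                      **kw) -> list[FeatureWindow]:
    """Extract windows for many genes, skipping (with a warning) genes whose
    window overruns a chromosome end."""
    out = []
    for g in genes:
        try:
            out.append(extract_window(tracks, g, context, **kw))
        except TrackError as err:
            logger.warning("skipping %s: %s", g.gene_id, err)
    return out
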