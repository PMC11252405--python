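"""Per-gene omics features: promoter signal densities and variant frequencies.

Coordinates are 0-based, half-open (BED convention) throughout.  The
transcription start site (TSS) of a gene is its strand-aware edge: ``start``
for ``+`` genes, ``end`` for ``-`` genes.  Promoter signal for an epigenomic
mark (ATAC, CTCF, H3K4me3, H3K27ac, ...) is the length-weighted mean signal
over the window TSS ± ``flank`` bp, with uncovered bases contributing zero.

Variant frequencies follow the cross-sample averaging convention:

* CNV feature of gene *i*:  ``sum_s v[s, i] / |S|`` — the per-sample
  copy-number values averaged over the sample set *S*.
* SNV feature of gene *i*:  ``magnify * sum_s v[s, i] / (|S| * len_i)`` —
  non-silent mutation counts, length-normalized and averaged over samples,
  then magnified (default ×1000) to a usable feature scale.  Records whose
  classification is in ``silent_classes`` (default ``{"Silent"}``) are
  removed first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneTable",
    "SignalTrack",
    "read_gene_table",
    "read_bedgraph",
    "read_signal_track",
    "read_variant_table",
    "promoter_window",
    "promoter_density",
    "cnv_frequency",
    "snv_frequency",
]

DEFAULT_FLANK = 1000
DEFAULT_MAGNIFY = 1000.0
DEFAULT_SILENT_CLASSES = frozenset({"Silent"})


@dataclass
class GeneTable:
    """Gene annotation with strand-aware TSS.

    ``df`` columns: gene_id, chrom, start, end, strand, tss.
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if self.df["gene_id"].duplicated().any():
            raise ValueError("gene_ids must be unique")
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("gene start must be < end")
        if "tss" not in self.df.columns:
            self.df = self.df.assign(
                tss=np.where(self.df["strand"] == "+", self.df["start"], self.df["end"])
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.df["gene_id"].tolist()

    def lengths(self) -> pd.Series:
        return (self.df["end"] - self.df["start"]).set_axis(self.df["gene_id"])


@dataclass
class SignalTrack:
    """Non-overlapping signal intervals for one mark replicate.

    ``intervals`` columns: chrom, start, end, value.
    """

    intervals: pd.DataFrame
    mark_name: str = "signal"
    _by_chrom: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        iv = self.intervals
        if (iv["value"] < 0).any() or not np.isfinite(iv["value"]).all():
            raise ValueError("signal values must be finite and >= 0")
        for chrom, sub in iv.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            if (sub["end"].to_numpy()[:-1] > sub["start"].to_numpy()[1:]).any():
                raise ValueError(f"overlapping intervals on {chrom}")
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["value"].to_numpy(np.float64),
            )


def read_gene_table(path) -> GeneTable:
    """Read a BED6-like TSV: chrom, start, end, gene_id, score, strand."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str},
        comment="#",
    )
    return GeneTable(df[["gene_id", "chrom", "start", "end", "strand"]].copy())


def read_bedgraph(path, mark_name: str = "signal") -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str}, comment="#",
    )
    return SignalTrack(df, mark_name=mark_name)


def read_signal_track(path, mark_name: str = "signal") -> SignalTrack:
    """Read a bedGraph or bigWig file into a SignalTrack."""
    path = str(path)
    if path.endswith((".bw", ".bigwig", ".bigWig")):
        import pyBigWig  # optional dependency

        bw = pyBigWig.open(path)
        rows = []
        for chrom in bw.chroms():
            for start, end, value in bw.intervals(chrom) or []:
                rows.append((chrom, start, end, value))
        bw.close()
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        return SignalTrack(df, mark_name=mark_name)
    return read_bedgraph(path, mark_name=mark_name)


def read_variant_table(path) -> pd.DataFrame:
    """Read a variant TSV with header: sample_id, gene_id, kind, value[, snv_class]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    required = {"sample_id", "gene_id", "kind", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if (df["value"] < 0).any():
        raise ValueError("variant values must be >= 0")
    return df


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def promoter_window(tss: int, flank: int = DEFAULT_FLANK) -> tuple[int, int]:
    """Half-open promoter window [tss - flank, tss + flank), clipped at 0."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    return max(0, int(tss) - flank), int(tss) + flank


def promoter_density(
    track: SignalTrack, genes: GeneTable, flank: int = DEFAULT_FLANK
) -> np.ndarray:
    """Length-weighted mean signal over each gene's promoter window.

    Uncovered bases count as zero signal; the divisor is the full window
    width, so the result does not depend on how a constant-value region is
    split into abutting intervals.  Genes on chromosomes absent from the
    track get 0 with a warning.
    """
    if track.intervals.empty:
        warnings.warn("empty signal track; promoter densities are all zero")
        return np.zeros(len(genes.df))
    out = np.zeros(len(genes.df))
    track_chroms = set(track._by_chrom)
    missing_chroms = set(genes.df["chrom"]) - track_chroms
    if missing_chroms:
        warnings.warn(
            f"chromosomes absent from track {track.mark_name}: {sorted(missing_chroms)}"
        )
    for pos, (chrom, tss) in enumerate(zip(genes.df["chrom"], genes.df["tss"])):
        if chrom not in track._by_chrom:
            continue
        w_start, w_end = promoter_window(tss, flank)
        starts, ends, values = track._by_chrom[chrom]
        lo = np.searchsorted(ends, w_start, side="right")
        hi = np.searchsorted(starts, w_end, side="left")
        if lo >= hi:
            continue
        overlap = np.minimum(ends[lo:hi], w_end) - np.maximum(starts[lo:hi], w_start)
        out[pos] = float(np.dot(overlap, values[lo:hi])) / (w_end - w_start)
    return out


def _per_gene_sums(variants: pd.DataFrame, kind: str) -> tuple[pd.Series, int]:
    sub = variants[variants["kind"] == kind]
    n_samples = variants["sample_id"].nunique()
    if n_samples == 0:
        raise ValueError("no samples")
    return sub.groupby("gene_id")["value"].sum(), n_samples


def cnv_frequency(variants: pd.DataFrame, genes: GeneTable) -> np.ndarray:
    """Average per-sample copy-number value for each gene (zeros if absent)."""
    sums, n_samples = _per_gene_sums(variants, "CNV")
    return (
        sums.reindex(genes.gene_ids).fillna(0.0).to_numpy() / n_samples
    )


def snv_frequency(
    variants: pd.DataFrame,
    genes: GeneTable,
    magnify: float = DEFAULT_MAGNIFY,
    silent_classes: frozenset[str] = DEFAULT_SILENT_CLASSES,
) -> np.ndarray:
    """Length-normalized, cross-sample-averaged non-silent mutation rate.

    ``x_i = magnify * sum_s v[s, i] / (|S| * len_i)`` after dropping records
    whose ``snv_class`` is in ``silent_classes``.
    """
    lengths = genes.lengths()
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    # |S| is the full sample set, counted before the silent filter
    n_samples = variants["sample_id"].nunique()
    if n_samples == 0:
        raise ValueError("no samples")
    df = variants
    if "snv_class" in df.columns:
        df = df[~df["snv_class"].isin(silent_classes)]
    else:
        warnings.warn("no snv_class column; treating all SNVs as non-silent")
    sums = df[df["kind"] == "SNV"].groupby("gene_id")["value"].sum()
    per_gene = sums.reindex(genes.gene_ids).fillna(0.0).to_numpy()
    return magnify * per_gene / (n_samples * lengths.to_numpy())
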