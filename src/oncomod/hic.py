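"""Hi-C preprocessing: ICE balancing, gene contact matrices, SVD condensation.

A genome-wide binned contact matrix ``H`` (counts ``h_ab`` between fixed-size
bins) is balanced by iterative correction so that all nonzero row/column
marginals are equal, mapped to a symmetric gene x gene contact matrix ``C``
(``c_ij`` = sum of ``h_ab`` over all bin pairs overlapping the two gene
bodies), and condensed by truncated SVD into a small number of per-gene
coordinates (default 5) used as node features downstream.

The module also provides the alternative "contacts as edges" graph builders
(unweighted / log10 / tenth-root weights) and a binomial read-depth
downsampler for robustness experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .features import GeneTable

__all__ = [
    "ContactMatrix",
    "GeneContactMatrix",
    "HiCFeatures",
    "HiCSVDCondenser",
    "read_contact_matrix",
    "write_contact_matrix",
    "ice_normalize",
    "gene_contact_matrix",
    "svd_condense",
    "hic_edge_graph",
    "downsample_contacts",
]

SYMMETRY_TOL = 1e-9


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix with its bin table."""

    bins: pd.DataFrame  # columns: chrom, start
    H: np.ndarray
    resolution: int

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=np.float64)
        if self.H.ndim != 2 or self.H.shape[0] != self.H.shape[1]:
            raise ValueError("H must be square")
        if self.H.shape[0] != len(self.bins):
            raise ValueError("bin count does not match matrix dimension")
        if not np.allclose(self.H, self.H.T, atol=SYMMETRY_TOL):
            raise ValueError("H must be symmetric")
        if (self.H < 0).any():
            raise ValueError("contact counts must be >= 0")

    @property
    def n_bins(self) -> int:
        return self.H.shape[0]


@dataclass
class GeneContactMatrix:
    """Symmetric gene x gene contact sums with per-gene bin ranges."""

    gene_ids: list[str]
    C: np.ndarray
    gene_bin_ranges: dict[str, tuple[int, int]]  # half-open bin index ranges

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.C.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("C dimension must equal number of genes")
        if not np.allclose(self.C, self.C.T, atol=SYMMETRY_TOL):
            raise ValueError("C must be symmetric")


@dataclass
class HiCFeatures:
    """Condensed per-gene contact-matrix coordinates (gene x k)."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("condensed features must be finite")


# ---------------------------------------------------------------------------
# IO: sparse 3-column TSV (bin_a, bin_b, count) + bins BED (chrom, start, end)
# ---------------------------------------------------------------------------

def read_contact_matrix(pixels_path, bins_path, resolution: int) -> ContactMatrix:
    bins = pd.read_csv(
        bins_path, sep="\t", header=None, names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )[["chrom", "start"]]
    px = pd.read_csv(
        pixels_path, sep="\t", header=None, names=["bin_a", "bin_b", "count"]
    )
    n = len(bins)
    H = np.zeros((n, n))
    a = px["bin_a"].to_numpy(np.intp)
    b = px["bin_b"].to_numpy(np.intp)
    c = px["count"].to_numpy(np.float64)
    np.add.at(H, (a, b), c)
    off = a != b
    np.add.at(H, (b[off], a[off]), c[off])
    return ContactMatrix(bins=bins, H=H, resolution=resolution)


def write_contact_matrix(cm: ContactMatrix, pixels_path, bins_path) -> None:
    n = cm.n_bins
    bins = cm.bins.assign(end=cm.bins["start"] + cm.resolution)
    bins[["chrom", "start", "end"]].to_csv(bins_path, sep="\t", header=False, index=False)
    iu = np.triu_indices(n)
    mask = cm.H[iu] != 0
    pd.DataFrame(
        {"bin_a": iu[0][mask], "bin_b": iu[1][mask], "count": cm.H[iu][mask]}
    ).to_csv(pixels_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def ice_normalize(
    cm: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> ContactMatrix:
    """Iterative correction: equalize nonzero row/column marginals.

    Rows that are entirely zero are excluded from the iteration and stay
    zero.  Convergence is reached when the coefficient of variation of the
    nonzero-row marginals drops below ``tol``.
    """
    H = cm.H.copy()
    if not H.any():
        raise ValueError("empty contact matrix")
    nonzero = H.sum(axis=1) > 0
    for _ in range(max_iter):
        marg = H.sum(axis=1)
        m = marg[nonzero]
        cv = m.std() / m.mean()
        if cv < tol:
            break
        scale = np.ones_like(marg)
        scale[nonzero] = m / m.mean()
        H = H / np.outer(scale, scale)
    return ContactMatrix(bins=cm.bins, H=H, resolution=cm.resolution)


def _gene_bin_range(cm: ContactMatrix, chrom: str, start: int, end: int):
    """Half-open range of bin indices whose bins overlap [start, end)."""
    sub = cm.bins.index[cm.bins["chrom"] == chrom]
    if len(sub) == 0:
        return None
    starts = cm.bins.loc[sub, "start"].to_numpy()
    lo = np.searchsorted(starts, start - cm.resolution, side="right")
    hi = np.searchsorted(starts, end, side="left")
    if lo >= hi:
        return None
    return int(sub[lo]), int(sub[hi - 1]) + 1


def gene_contact_matrix(cm: ContactMatrix, genes: GeneTable) -> GeneContactMatrix:
    """Sum ``h_ab`` over all bin pairs covering each pair of gene bodies."""
    gene_ids = genes.gene_ids
    n = len(gene_ids)
    ranges: dict[str, tuple[int, int]] = {}
    missing = []
    slices: list[slice | None] = []
    for gid, chrom, start, end in zip(
        gene_ids, genes.df["chrom"], genes.df["start"], genes.df["end"]
    ):
        rng = _gene_bin_range(cm, chrom, int(start), int(end))
        if rng is None:
            missing.append(gid)
            slices.append(None)
        else:
            ranges[gid] = rng
            slices.append(slice(*rng))
    if missing:
        warnings.warn(f"{len(missing)} genes overlap no Hi-C bin; rows set to zero")
    # row sums within each gene's bin range, then column sums: C = R H R^T
    R = np.zeros((n, cm.n_bins))
    for i, sl in enumerate(slices):
        if sl is not None:
            R[i, sl] = 1.0
    C = R @ cm.H @ R.T
    C = (C + C.T) / 2  # enforce exact symmetry against float noise
    return GeneContactMatrix(gene_ids=gene_ids, C=C, gene_bin_ranges=ranges)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic SVD sign convention: largest-|entry| of each column > 0."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def svd_condense(gcm: GeneContactMatrix, k: int = 5) -> HiCFeatures:
    """Truncated SVD of C; per-gene features are ``(U_k @ diag(s_k))[i]``."""
    n = len(gcm.gene_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    C = gcm.C
    if not C.any():
        return HiCFeatures(gene_ids=gcm.gene_ids, values=np.zeros((n, k)))
    if n > 200 and k < n - 1:
        # sparse truncated SVD with a fixed start vector for determinism
        U, s, _ = spla.svds(sp.csr_matrix(C), k=k, v0=np.ones(n))
        order = np.argsort(s)[::-1]
        U, s = U[:, order], s[order]
    else:
        U, s, _ = np.linalg.svd(C)
        U, s = U[:, :k], s[:k]
    U = U * _fix_signs(U)
    return HiCFeatures(gene_ids=gcm.gene_ids, values=U * s)


class HiCSVDCondenser:
    """Transformer-style wrapper around :func:`svd_condense`.

    ``fit_transform`` accepts a :class:`GeneContactMatrix` (or a symmetric
    array) and returns the gene x k condensed coordinate matrix.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "HiCSVDCondenser":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "HiCSVDCondenser":
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        if not isinstance(X, GeneContactMatrix):
            X = np.asarray(X, dtype=np.float64)
            X = GeneContactMatrix(
                gene_ids=[str(i) for i in range(X.shape[0])], C=X, gene_bin_ranges={}
            )
        feats = svd_condense(X, k=self.n_components)
        self.embedding_ = feats.values
        self.gene_ids_ = feats.gene_ids
        return self.embedding_

    def transform(self, X) -> np.ndarray:
        return self.fit_transform(X)


def hic_edge_graph(
    gcm: GeneContactMatrix, mode: str = "unweighted", threshold: float = 0.0
) -> nx.Graph:
    """Build a gene graph from contacts instead of using them as features.

    ``unweighted``: edge iff c_ij > threshold (weight 1); ``log10``: weight
    ``log10(1 + c_ij)`` (the +1 keeps sub-unit balanced contacts finite);
    ``tenth_root``: weight ``c_ij ** 0.1``.  No self-loops.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if mode not in {"unweighted", "log10", "tenth_root"}:
        raise ValueError(f"unknown mode: {mode!r}")
    G = nx.Graph()
    G.add_nodes_from(gcm.gene_ids)
    n = len(gcm.gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    c = gcm.C[iu, ju]
    keep = c > threshold
    for i, j, cij in zip(iu[keep], ju[keep], c[keep]):
        if mode == "unweighted":
            w = 1.0
        elif mode == "log10":
            w = float(np.log10(1.0 + cij))
        else:
            w = float(cij**0.1)
        G.add_edge(gcm.gene_ids[i], gcm.gene_ids[j], weight=w)
    return G


def downsample_contacts(cm: ContactMatrix, rate: float, seed: int) -> ContactMatrix:
    """Binomially thin each contact count to a fraction ``rate`` of reads.

    The upper triangle (incl. diagonal) is drawn and mirrored, preserving
    symmetry; expected total equals ``rate`` x original total.  Counts are
    floored to integers before drawing.
    """
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    if rate == 1.0:
        return ContactMatrix(bins=cm.bins, H=cm.H.copy(), resolution=cm.resolution)
    rng = np.random.default_rng(seed)
    n = cm.n_bins
    H = np.zeros((n, n))
    iu = np.triu_indices(n)
    drawn = rng.binomial(cm.H[iu].astype(np.int64), rate).astype(np.float64)
    H[iu] = drawn
    H.T[iu] = drawn
    return ContactMatrix(bins=cm.bins, H=H, resolution=cm.resolution)
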