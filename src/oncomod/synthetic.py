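"""Seeded generator of a complete synthetic multi-omics dataset.

The generator emulates the statistical structure of the real inputs —
gene annotation, promoter signal tracks, per-sample SNV/CNV tables, a binned
Hi-C contact matrix, a confidence-scored PPI edge list, and tri-state labels
— with a planted, tunable association between the positive class and
(i) the SNV mutation rate (``snv_effect``, in SD units of the background
rate distribution), (ii) promoter signal (``track_effect``, in SD units),
(iii) PPI homophily (``edge_enrichment``: extra positive-positive edges),
and (iv) spatial co-location (``hic_block_strength``: positives
preferentially placed in the same genomic communities, whose bins get
proportionally boosted Hi-C contact blocks).

Genes are laid head-to-tail on a few synthetic chromosomes with >=2 kb
intergenic gaps (so +/-1 kb promoter windows never overlap), grouped into
``n_communities`` contiguous communities that double as Hi-C contact blocks
and PPI communities.  Hi-C counts are Poisson draws around a power-law
distance decay (exponent -1) plus a weak inter-chromosomal background.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .features import GeneTable, SignalTrack
from .graph import BLOCK_LAYOUTS
from .hic import ContactMatrix, write_contact_matrix

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "null_config", "toy_fixtures"]


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    n_positive: int = 200
    n_negative: int = 600
    n_samples: int = 50
    ppi_model: str = "community"  # or "scale-free"
    n_communities: int = 20
    hic_block_strength: float = 1.0
    snv_effect: float = 2.0  # mean shift of positive-gene SNV rate, in SDs
    track_effect: float = 1.0  # mean shift of positive-gene promoter signal, in SDs
    edge_enrichment: float = 4.0  # positive-positive edge odds multiplier
    resolution: int = 25_000
    seed: int = 0
    n_chromosomes: int = 4
    mode: str = "cell_line"
    hic_depth: float = 20.0  # expected diagonal contact count per bin
    snv_rate_mean: float = 0.06  # background SNV feature scale (x1000 magnified)
    snv_rate_sd: float = 0.02
    mean_within_degree: float = 6.0
    mean_between_degree: float = 2.0

    def __post_init__(self):
        if self.n_positive + self.n_negative > self.n_genes:
            raise ValueError("more labeled genes than genes")
        for name in ("hic_block_strength", "snv_effect", "track_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.edge_enrichment < 1:
            raise ValueError("edge_enrichment must be >= 1 (1 = no enrichment)")
        if self.ppi_model not in {"community", "scale-free"}:
            raise ValueError(f"unknown ppi_model: {self.ppi_model!r}")
        if self.n_positive > 0 and self.n_genes // self.n_communities == 0:
            raise ValueError("communities have no capacity")


def null_config(**overrides) -> SyntheticConfig:
    """A configuration with no planted label signal (for calibration runs)."""
    base = dict(
        hic_block_strength=0.0, snv_effect=0.0, track_effect=0.0,
        edge_enrichment=1.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    gene_table: GeneTable
    tracks: dict[str, list[SignalTrack]]  # mark -> replicate tracks
    variants: pd.DataFrame
    contact_matrix: ContactMatrix
    ppi: pd.DataFrame  # gene_a, gene_b, score
    labels: pd.Series  # gene_id -> {1, 0, -1}
    truth: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gdf = self.gene_table.df
        gdf.assign(score=0)[["chrom", "start", "end", "gene_id", "score", "strand"]] \
            .to_csv(outdir / "genes.bed", sep="\t", header=False, index=False)
        for mark, reps in self.tracks.items():
            for r, track in enumerate(reps):
                track.intervals.to_csv(
                    outdir / f"{mark}_rep{r}.bedgraph", sep="\t",
                    header=False, index=False,
                )
        self.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        write_contact_matrix(
            self.contact_matrix, outdir / "hic_pixels.tsv", outdir / "hic_bins.bed"
        )
        self.ppi.to_csv(outdir / "ppi.tsv", sep="\t", header=False, index=False)
        self.labels.rename("label").rename_axis("gene_id").reset_index().to_csv(
            outdir / "labels.tsv", sep="\t", index=False
        )
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config), fh, sort_keys=True)


def _lay_out_genes(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1
    rows = []
    gid = 0
    for c, count in enumerate(per_chrom):
        pos = int(rng.integers(2000, 8000))
        for _ in range(count):
            length = int(np.clip(rng.lognormal(np.log(20_000), 0.4), 3_000, 120_000))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"g{gid:05d}", f"chr{c + 1}", pos, pos + length, strand))
            pos += length + int(rng.integers(2_000, 12_000))
            gid += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _plant_labels(cfg: SyntheticConfig, communities: np.ndarray,
                  rng: np.random.Generator):
    n_cancer_comms = max(1, cfg.n_communities // 4)
    cancer_comms = np.sort(
        rng.choice(cfg.n_communities, size=n_cancer_comms, replace=False)
    )
    weights = np.where(
        np.isin(communities, cancer_comms), 1.0 + 2.0 * cfg.hic_block_strength, 1.0
    )
    weights = weights / weights.sum()
    positives = np.sort(
        rng.choice(cfg.n_genes, size=cfg.n_positive, replace=False, p=weights)
    )
    rest = np.setdiff1d(np.arange(cfg.n_genes), positives)
    negatives = np.sort(rng.choice(rest, size=cfg.n_negative, replace=False))
    labels = np.full(cfg.n_genes, -1, dtype=np.int64)
    labels[positives] = 1
    labels[negatives] = 0
    return labels, positives, negatives, cancer_comms


def _make_ppi(cfg: SyntheticConfig, communities: np.ndarray, is_pos: np.ndarray,
              rng: np.random.Generator) -> set[tuple[int, int]]:
    n = cfg.n_genes
    edges: set[tuple[int, int]] = set()
    if cfg.ppi_model == "community":
        comm_size = max(2, n // cfg.n_communities)
        p_in = min(1.0, cfg.mean_within_degree / (comm_size - 1))
        for c in range(cfg.n_communities):
            members = np.flatnonzero(communities == c)
            m = len(members)
            if m < 2:
                continue
            iu, ju = np.triu_indices(m, k=1)
            hit = rng.random(len(iu)) < p_in
            edges.update(zip(members[iu[hit]], members[ju[hit]]))
        n_between = rng.poisson(cfg.mean_between_degree * n / 2)
        a = rng.integers(0, n, size=2 * n_between)
        b = rng.integers(0, n, size=2 * n_between)
        for i, j in zip(a, b):
            if i != j and communities[i] != communities[j]:
                edges.add((min(i, j), max(i, j)))
    else:  # scale-free
        G = nx.barabasi_albert_graph(n, 3, seed=int(rng.integers(2**31)))
        edges.update((min(u, v), max(u, v)) for u, v in G.edges())
    # positive-positive homophily: extra edges among positives
    if cfg.edge_enrichment > 1 and is_pos.sum() > 1:
        pos_idx = np.flatnonzero(is_pos)
        p_add = min(0.5, (cfg.edge_enrichment - 1.0) * 1.5 / max(1, len(pos_idx)))
        iu, ju = np.triu_indices(len(pos_idx), k=1)
        hit = rng.random(len(iu)) < p_add
        edges.update(zip(pos_idx[iu[hit]], pos_idx[ju[hit]]))
    return edges


def _make_hic(cfg: SyntheticConfig, genes: pd.DataFrame, communities: np.ndarray,
              rng: np.random.Generator) -> ContactMatrix:
    bin_rows = []
    bin_comm = []
    for c, sub in genes.groupby("chrom", sort=False):
        chrom_len = int(sub["end"].max()) + cfg.resolution
        starts = np.arange(0, chrom_len, cfg.resolution)
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2
        order = np.argsort(mids)
        nearest = np.clip(
            np.searchsorted(mids[order], starts + cfg.resolution / 2),
            0, len(sub) - 1,
        )
        comm_of = communities[sub.index.to_numpy()][order][nearest]
        for s, cm in zip(starts, comm_of):
            bin_rows.append((c, int(s)))
            bin_comm.append(cm)
    bins = pd.DataFrame(bin_rows, columns=["chrom", "start"])
    bin_comm = np.asarray(bin_comm)
    nb = len(bins)
    chrom_codes = bins["chrom"].astype("category").cat.codes.to_numpy()
    idx_in_chrom = np.zeros(nb, dtype=np.int64)
    for c in np.unique(chrom_codes):
        sel = chrom_codes == c
        idx_in_chrom[sel] = np.arange(sel.sum())
    same_chrom = chrom_codes[:, None] == chrom_codes[None, :]
    dist = np.abs(idx_in_chrom[:, None] - idx_in_chrom[None, :])
    lam = np.where(same_chrom, cfg.hic_depth / (dist + 1.0), 0.05)
    same_comm = bin_comm[:, None] == bin_comm[None, :]
    lam = lam * np.where(same_comm & same_chrom, 1.0 + cfg.hic_block_strength, 1.0)
    H = np.zeros((nb, nb))
    iu = np.triu_indices(nb)
    drawn = rng.poisson(lam[iu]).astype(np.float64)
    H[iu] = drawn
    H.T[iu] = drawn
    return ContactMatrix(bins=bins, H=H, resolution=cfg.resolution)


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset bundle for a configuration (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    genes = _lay_out_genes(cfg, rng)
    gene_table = GeneTable(genes)
    communities = (np.arange(cfg.n_genes) * cfg.n_communities) // cfg.n_genes
    labels, positives, negatives, cancer_comms = _plant_labels(cfg, communities, rng)
    is_pos = labels == 1

    # promoter tracks: one replicate per layout column, Gamma(2, 1) baseline
    track_sd = np.sqrt(2.0)
    tracks: dict[str, list[SignalTrack]] = {}
    tss = gene_table.df["tss"].to_numpy()
    chrom = gene_table.df["chrom"].to_numpy()
    for mark, width in BLOCK_LAYOUTS[cfg.mode].items():
        if mark == "HiC":
            continue
        reps = []
        for _ in range(width):
            signal = rng.gamma(2.0, 1.0, size=cfg.n_genes)
            signal = signal + is_pos * cfg.track_effect * track_sd
            iv = pd.DataFrame({
                "chrom": chrom,
                "start": np.maximum(0, tss - 1000),
                "end": tss + 1000,
                "value": signal,
            }).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
            reps.append(SignalTrack(iv, mark_name=mark))
        tracks[mark] = reps

    # variants: Poisson SNV counts around a planted per-gene rate, neutral CNV
    lengths = (genes["end"] - genes["start"]).to_numpy()
    snv_rate = np.clip(
        rng.normal(cfg.snv_rate_mean, cfg.snv_rate_sd, size=cfg.n_genes), 1e-4, None
    )
    snv_rate = snv_rate + is_pos * cfg.snv_effect * cfg.snv_rate_sd
    lam = snv_rate * lengths / 1000.0
    sample_ids = [f"s{j:03d}" for j in range(cfg.n_samples)]
    snv_counts = rng.poisson(np.broadcast_to(lam, (cfg.n_samples, cfg.n_genes)))
    silent_counts = rng.poisson(
        np.broadcast_to(0.3 * lam, (cfg.n_samples, cfg.n_genes))
    )
    cnv_values = np.clip(
        rng.normal(2.0, 0.5, size=(cfg.n_samples, cfg.n_genes)), 0.0, None
    )
    frames = []
    gene_ids = genes["gene_id"].to_numpy()
    for kind, values, snv_class in (
        ("SNV", snv_counts, "Missense_Mutation"),
        ("SNV", silent_counts, "Silent"),
        ("CNV", cnv_values, ""),
    ):
        s_idx, g_idx = np.nonzero(values)
        frames.append(pd.DataFrame({
            "sample_id": np.array(sample_ids)[s_idx],
            "gene_id": gene_ids[g_idx],
            "kind": kind,
            "value": values[s_idx, g_idx],
            "snv_class": snv_class,
        }))
    variants = pd.concat(frames, ignore_index=True)

    cm = _make_hic(cfg, genes, communities, rng)

    edge_set = _make_ppi(cfg, communities, is_pos, rng)
    edge_arr = np.array(sorted(edge_set), dtype=np.int64).reshape(-1, 2)
    ppi = pd.DataFrame({
        "gene_a": gene_ids[edge_arr[:, 0]],
        "gene_b": gene_ids[edge_arr[:, 1]],
        "score": rng.uniform(0.5, 1.0, size=len(edge_arr)),
    })
    # decoy low-confidence edges, removed by the score filter downstream
    n_decoy = max(1, len(edge_arr) // 20)
    da = rng.integers(0, cfg.n_genes, size=n_decoy)
    db = rng.integers(0, cfg.n_genes, size=n_decoy)
    keep = da != db
    decoys = pd.DataFrame({
        "gene_a": gene_ids[da[keep]],
        "gene_b": gene_ids[db[keep]],
        "score": rng.uniform(0.0, 0.5, size=keep.sum()) * 0.999,
    })
    ppi = pd.concat([ppi, decoys], ignore_index=True)

    truth = {
        "positives": gene_ids[positives].tolist(),
        "negatives": gene_ids[negatives].tolist(),
        "cancer_communities": cancer_comms.tolist(),
        "communities": communities.tolist(),
        "snv_rate_mean": cfg.snv_rate_mean,
        "snv_rate_sd": cfg.snv_rate_sd,
        "snv_effect": cfg.snv_effect,
        "track_effect": cfg.track_effect,
        "edge_enrichment": cfg.edge_enrichment,
        "seed": cfg.seed,
    }
    return SyntheticDataset(
        config=cfg,
        gene_table=gene_table,
        tracks=tracks,
        variants=variants,
        contact_matrix=cm,
        ppi=ppi,
        labels=pd.Series(labels, index=gene_ids, name="label"),
        truth=truth,
    )


def toy_fixtures() -> dict:
    """Tiny named inputs used across the unit tests (deterministic)."""
    hic_bins = pd.DataFrame({
        "chrom": ["chr1"] * 3, "start": [0, 100, 200],
    })
    return {
        "path4": nx.path_graph(["a", "b", "c", "d"]),
        "star5": nx.star_graph(4),
        "triangle": nx.cycle_graph(3),
        "hic3": ContactMatrix(
            bins=hic_bins,
            H=np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]]),
            resolution=100,
        ),
        "scores4": (np.array([0.9, 0.8, 0.4, 0.2]), np.array([1, 0, 1, 0])),
    }
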