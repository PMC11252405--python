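"""High-level assembly: raw inputs -> feature blocks -> multi-omics graph.

Stage order mirrors the preprocessing pipeline: (structural-variant
correction of Hi-C is an external pre-step) -> ICE balancing -> gene contact
matrix -> SVD condensation, alongside promoter densities and variant
frequencies, then per-column z-scoring and concatenation into the node
feature matrix of the PPI graph.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    GeneTable,
    promoter_density,
    cnv_frequency,
    snv_frequency,
    read_gene_table,
    read_signal_track,
    read_variant_table,
)
from .graph import (
    BLOCK_LAYOUTS,
    MultiOmicsGraph,
    assemble_features,
    condense_network,
    load_ppi,
    read_labels,
)
from .hic import gene_contact_matrix, ice_normalize, read_contact_matrix, svd_condense
from .synthetic import SyntheticDataset

__all__ = ["compute_feature_blocks", "build_graph", "load_dataset_dir"]


def compute_feature_blocks(
    dataset: SyntheticDataset | dict,
    mode: str = "cell_line",
    flank: int = 1000,
    svd_k: int = 5,
    ice: bool = True,
) -> dict[str, np.ndarray]:
    """Per-gene feature blocks, keyed and shaped per the mode's layout."""
    genes: GeneTable = dataset.gene_table if isinstance(dataset, SyntheticDataset) \
        else dataset["gene_table"]
    tracks = dataset.tracks if isinstance(dataset, SyntheticDataset) else dataset["tracks"]
    variants = dataset.variants if isinstance(dataset, SyntheticDataset) \
        else dataset.get("variants")
    cm = dataset.contact_matrix if isinstance(dataset, SyntheticDataset) \
        else dataset["contact_matrix"]

    layout = BLOCK_LAYOUTS[mode]
    blocks: dict[str, np.ndarray] = {}
    for mark, width in layout.items():
        if mark == "HiC":
            continue
        if mark in ("CNV", "SNV"):
            if variants is None:
                raise ValueError(f"mode {mode!r} requires a variant table ({mark})")
            if mark == "CNV":
                blocks["CNV"] = cnv_frequency(variants, genes)
            else:
                blocks["SNV"] = snv_frequency(variants, genes)
            continue
        reps = tracks[mark]
        if len(reps) != width:
            raise ValueError(
                f"mark {mark!r} needs {width} replicate tracks, got {len(reps)}"
            )
        blocks[mark] = np.column_stack(
            [promoter_density(t, genes, flank=flank) for t in reps]
        )
    balanced = ice_normalize(cm) if ice else cm
    gcm = gene_contact_matrix(balanced, genes)
    blocks["HiC"] = svd_condense(gcm, k=svd_k).values
    return blocks


def build_graph(
    dataset: SyntheticDataset | dict,
    mode: str = "cell_line",
    flank: int = 1000,
    svd_k: int = 5,
    ppi_threshold: float = 0.5,
    normalize: bool = True,
    condense: bool = True,
    ice: bool = True,
) -> MultiOmicsGraph:
    """Assemble the full semi-supervised graph from a dataset bundle."""
    genes = dataset.gene_table if isinstance(dataset, SyntheticDataset) \
        else dataset["gene_table"]
    ppi = dataset.ppi if isinstance(dataset, SyntheticDataset) else dataset["ppi"]
    labels = dataset.labels if isinstance(dataset, SyntheticDataset) \
        else dataset["labels"]
    blocks = compute_feature_blocks(
        dataset, mode=mode, flank=flank, svd_k=svd_k, ice=ice
    )
    X = assemble_features(blocks, mode=mode, normalize=normalize)
    gene_ids = genes.gene_ids
    known = set(gene_ids)
    edges = [(a, b) for a, b in load_ppi(ppi, ppi_threshold)
             if a in known and b in known]
    y = pd.Series(labels).reindex(gene_ids).fillna(-1).astype(int).to_numpy()
    graph = MultiOmicsGraph(
        gene_ids=gene_ids, edges=edges, X=X, y=y, mode=mode,
        block_widths=dict(BLOCK_LAYOUTS[mode]),
    )
    return condense_network(graph) if condense else graph


def load_dataset_dir(path, mode: str = "cell_line") -> dict:
    """Read a written dataset directory back into the in-memory bundle."""
    path = Path(path)
    gene_table = read_gene_table(path / "genes.bed")
    tracks: dict[str, list] = {}
    for mark, width in BLOCK_LAYOUTS[mode].items():
        if mark == "HiC":
            continue
        if mark in ("CNV", "SNV"):
            continue
        tracks[mark] = [
            read_signal_track(path / f"{mark}_rep{r}.bedgraph", mark_name=mark)
            for r in range(width)
        ]
    variants_path = path / "variants.tsv"
    variants = read_variant_table(variants_path) if variants_path.exists() else None
    import yaml

    with open(path / "config.yaml") as fh:
        resolution = yaml.safe_load(fh)["resolution"]
    cm = read_contact_matrix(
        path / "hic_pixels.tsv", path / "hic_bins.bed", resolution
    )
    labels = read_labels(path / "labels.tsv").set_index("gene_id")["label"]
    ppi = pd.read_csv(
        path / "ppi.tsv", sep="\t", header=None,
        names=["gene_a", "gene_b", "score"], dtype={"gene_a": str, "gene_b": str},
    )
    return {
        "gene_table": gene_table,
        "tracks": tracks,
        "variants": variants,
        "contact_matrix": cm,
        "ppi": ppi,
        "labels": labels,
    }
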