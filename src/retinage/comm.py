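"""Aging ligand-receptor differential communication networks.

For each cell type, every gene gets a scaled differential-expression
magnitude: |log2FC| between aged and adult cells of that type, z-scaled
across the type's genes.  An edge connects (ligand, sender type) to
(receptor, receiver type) when both genes clear an expression filter in
their respective types; its score is the sum of the two node magnitudes.
``top_k`` keeps the highest-scoring edges (the study's figures show the top
100), with a deterministic lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import (
    DEFAULT_STAGE_MAP,
    NormalizedMatrix,
    StageMap,
    log2_fold_change,
    _linear_means,
)
from .annotate import CellAnnotation

__all__ = [
    "LRDatabase",
    "CommGraph",
    "DEFAULT_LR_PAIRS",
    "de_magnitude",
    "build_network",
    "top_k",
]

# Small curated ligand-receptor fixture (classical retina-relevant pairs,
# VEGFA and its receptors included); any two/three-column TSV is accepted.
DEFAULT_LR_PAIRS: list[tuple[str, str]] = [
    ("VEGFA", "FLT1"),
    ("VEGFA", "KDR"),
    ("VEGFA", "NRP1"),
    ("BDNF", "NTRK2"),
    ("NGF", "NGFR"),
    ("TGFB1", "TGFBR1"),
    ("TGFB1", "TGFBR2"),
    ("APOE", "LRP1"),
    ("PSAP", "GPR37"),
    ("EFNA1", "EPHA4"),
    ("DLL1", "NOTCH1"),
    ("JAG1", "NOTCH2"),
    ("WNT5A", "FZD3"),
    ("SHH", "PTCH1"),
    ("IGF1", "IGF1R"),
    ("FGF2", "FGFR1"),
    ("PDGFB", "PDGFRB"),
    ("CX3CL1", "CX3CR1"),
    ("TNF", "TNFRSF1A"),
    ("IL34", "CSF1R"),
]


@dataclass
class LRDatabase:
    """Ligand-receptor pair table with unique pair ids."""

    pairs: pd.DataFrame  # columns ligand_gene, receptor_gene, pair_id

    def __post_init__(self) -> None:
        required = {"ligand_gene", "receptor_gene", "pair_id"}
        if not required <= set(self.pairs.columns):
            raise ValueError(f"LR table needs columns {sorted(required)}")
        if self.pairs.empty:
            raise ValueError("empty ligand-receptor database")
        if self.pairs["pair_id"].duplicated().any():
            dup = self.pairs.loc[self.pairs["pair_id"].duplicated(), "pair_id"]
            raise ValueError(f"duplicate pair_id(s): {dup.tolist()[:5]}")
        if (self.pairs["ligand_gene"].astype(str).str.len() == 0).any() or \
                (self.pairs["receptor_gene"].astype(str).str.len() == 0).any():
            raise ValueError("empty gene symbol in LR table")

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "LRDatabase":
        df = pd.DataFrame(pairs, columns=["ligand_gene", "receptor_gene"])
        df["pair_id"] = df["ligand_gene"] + "_" + df["receptor_gene"]
        return cls(df)

    @classmethod
    def default(cls) -> "LRDatabase":
        return cls.from_pairs(DEFAULT_LR_PAIRS)

    @classmethod
    def from_tsv(cls, path) -> "LRDatabase":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        if {"ligand_gene", "receptor_gene"} <= set(df.columns):
            pairs = df
        else:  # plain two-column file
            pairs = df.iloc[:, :2]
            pairs.columns = ["ligand_gene", "receptor_gene"]
        if "pair_id" not in pairs.columns:
            pairs = pairs.assign(
                pair_id=pairs["ligand_gene"] + "_" + pairs["receptor_gene"]
            )
        return cls(pairs)


@dataclass
class CommGraph:
    """Bipartite-by-role communication graph as an edge table.

    Edge rows: ``pair_id, ligand, receptor, sender, receiver, score,
    ligand_magnitude, receptor_magnitude``.  ``k_filter`` records a top-k
    truncation if one was applied.
    """

    edges: pd.DataFrame
    k_filter: int | None = None

    def __post_init__(self) -> None:
        required = {"pair_id", "ligand", "receptor", "sender", "receiver",
                    "score", "ligand_magnitude", "receptor_magnitude"}
        missing = required - set(self.edges.columns)
        if missing:
            raise ValueError(f"edge table missing columns {sorted(missing)}")
        if len(self.edges) and not np.all(np.isfinite(self.edges["score"])):
            raise ValueError("edge scores must be finite")
        if self.k_filter is not None and len(self.edges) > self.k_filter:
            raise ValueError("edge count exceeds the recorded k_filter")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes(self) -> pd.DataFrame:
        lig = self.edges[["ligand", "sender", "ligand_magnitude"]].rename(
            columns={"ligand": "gene", "sender": "cell_type",
                     "ligand_magnitude": "de_magnitude"})
        lig["role"] = "ligand"
        rec = self.edges[["receptor", "receiver", "receptor_magnitude"]].rename(
            columns={"receptor": "gene", "receiver": "cell_type",
                     "receptor_magnitude": "de_magnitude"})
        rec["role"] = "receptor"
        return pd.concat([lig, rec]).drop_duplicates(
            subset=["gene", "cell_type", "role"]).reset_index(drop=True)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for _, row in self.nodes().iterrows():
            g.add_node((row["cell_type"], row["gene"], row["role"]),
                       de_magnitude=float(row["de_magnitude"]))
        for _, e in self.edges.iterrows():
            g.add_edge(
                (e["sender"], e["ligand"], "ligand"),
                (e["receiver"], e["receptor"], "receptor"),
                score=float(e["score"]), pair_id=e["pair_id"],
            )
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = self.to_networkx()
        # GraphML wants string node ids
        mapping = {n: f"{n[0]}:{n[1]}:{n[2]}" for n in g.nodes}
        nx.write_graphml(nx.relabel_nodes(g, mapping), path)

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def de_magnitude(
    matrix: NormalizedMatrix,
    annot: CellAnnotation,
    cell_type: str,
    stages: pd.Series | np.ndarray | None = None,
    contrast: tuple[str, str] = ("aging", "adult"),
    stage_map: StageMap = DEFAULT_STAGE_MAP,
    signed: bool = False,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Scaled aging-contrast DE magnitude per gene within one cell type.

    Magnitude = |log2FC| of contrast[0] vs contrast[1] cells of the type
    (signed variant by flag), z-scaled across the type's genes; an all-zero
    profile scales to zeros.  Also reports the detection fraction of each
    gene across the type's contrast cells (for the expression filter).
    """
    if stages is None:
        labels = stage_map.assign_many(matrix.meta["age_years"].to_numpy())
    else:
        labels = np.asarray(stages, dtype=object)
    ct_mask = (annot.cells["cell_type"] == cell_type).to_numpy()
    masks = []
    for stage in contrast:
        m = ct_mask & (labels == stage)
        if not m.any():
            raise ValueError(
                f"cell type {cell_type!r} has no cells in stage {stage!r}"
            )
        masks.append(m)
    mean_hi = _linear_means(sp.csr_matrix(matrix.values[:, masks[0]]))
    mean_lo = _linear_means(sp.csr_matrix(matrix.values[:, masks[1]]))
    lfc = log2_fold_change(mean_hi, mean_lo, pseudocount)
    mag = lfc if signed else np.abs(lfc)
    sd = mag.std()
    scaled = np.zeros_like(mag) if sd == 0 else (mag - mag.mean()) / sd
    both = masks[0] | masks[1]
    sub = matrix.values[:, both]
    frac = np.asarray((sub > 0).sum(axis=1)).ravel() / int(both.sum())
    return pd.DataFrame(
        {"magnitude": scaled, "log2fc": lfc, "frac_expr": frac},
        index=pd.Index(matrix.gene_ids, name="gene"),
    )


def build_network(
    lr_db: LRDatabase,
    magnitudes_by_celltype: dict[str, pd.DataFrame],
    senders: list[str] | None = None,
    receivers: list[str] | None = None,
    expr_filter: float = 0.10,
) -> CommGraph:
    """Score every (ligand, sender) x (receptor, receiver) candidate edge.

    An edge exists when the ligand is detected in >= ``expr_filter`` of the
    sender's cells and the receptor in >= ``expr_filter`` of the receiver's;
    its score is the sum of the two scaled node magnitudes.
    """
    senders = sorted(magnitudes_by_celltype) if senders is None else senders
    receivers = sorted(magnitudes_by_celltype) if receivers is None else receivers
    missing = [t for t in (*senders, *receivers) if t not in magnitudes_by_celltype]
    if missing:
        raise ValueError(f"magnitudes missing for cell type(s) {sorted(set(missing))}")

    rows = []
    for _, pair in lr_db.pairs.iterrows():
        lig, rec, pid = pair["ligand_gene"], pair["receptor_gene"], pair["pair_id"]
        for s in senders:
            mag_s = magnitudes_by_celltype[s]
            if lig not in mag_s.index or mag_s.loc[lig, "frac_expr"] < expr_filter:
                continue
            for t in receivers:
                mag_t = magnitudes_by_celltype[t]
                if rec not in mag_t.index or \
                        mag_t.loc[rec, "frac_expr"] < expr_filter:
                    continue
                ml = float(mag_s.loc[lig, "magnitude"])
                mr = float(mag_t.loc[rec, "magnitude"])
                rows.append(
                    {"pair_id": pid, "ligand": lig, "receptor": rec,
                     "sender": s, "receiver": t, "score": ml + mr,
                     "ligand_magnitude": ml, "receptor_magnitude": mr}
                )
    edges = pd.DataFrame(
        rows, columns=["pair_id", "ligand", "receptor", "sender", "receiver",
                       "score", "ligand_magnitude", "receptor_magnitude"],
    )
    return CommGraph(edges=edges)


def top_k(graph: CommGraph, k: int = 100) -> CommGraph:
    """Retain the k highest-scoring edges (ties: lexicographic pair id,
    then sender, then receiver); k beyond the edge count retains all."""
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = graph.edges.sort_values(
        by=["score", "pair_id", "sender", "receiver"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).head(k).reset_index(drop=True)
    return CommGraph(edges=edges, k_filter=k)
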