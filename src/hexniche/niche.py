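"""Immune-spot calling and hex-neighborhood niche classification.

A spot is *immune cell-enriched* when the arithmetic mean of its log-normalized
expression over an immune marker panel exceeds a threshold (default 0.9,
strictly).  Non-immune spots are *adjacent* when they touch an immune spot in
the Visium six-neighbor hex contact neighborhood, otherwise *away*.  The three
classes partition the analyzed spots; each spot also carries its tissue
stratum (tumor / benign) for region-stratified contrasts.

The default marker panel covers four liver immune lineages (23 genes total):
Kupffer cells (resident macrophages), T cells, B/plasma cells, and NK plus
other cytotoxic lineages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix
from .spatial_io import SpotGrid

__all__ = [
    "DEFAULT_MARKER_PANEL",
    "MarkerPanel",
    "NicheConfig",
    "NicheLabels",
    "Contrast",
    "ContrastSet",
    "marker_score",
    "call_immune_spots",
    "hex_neighbors",
    "classify_niche",
    "build_contrasts",
    "CONTRAST_NAMES",
]

logger = logging.getLogger(__name__)

DEFAULT_MARKER_PANEL: dict[str, list[str]] = {
    "kupffer": ["CD68", "CD163", "LYZ", "C1QA", "AIF1"],
    "t_cell": ["CD3D", "CD2", "IL7R", "TRBC2", "CD69"],
    "b_plasma": ["IGKC", "JCHAIN", "CD79A", "CD27", "CD74"],
    "nk_other": ["CD4", "CD8A", "ITGAM", "NKG7", "KLRD1", "PRF1", "CD7", "TRDC"],
}

# offsets of the six hex-lattice contacts in (array_row, array_col) space
HEX_OFFSETS = ((0, -2), (0, 2), (-1, -1), (-1, 1), (1, -1), (1, 1))

CONTRAST_NAMES = (
    "tumor_adjacent_vs_away",
    "benign_adjacent_vs_away",
    "tumor_adjacent_vs_benign_adjacent",
)


@dataclass
class MarkerPanel:
    """Named immune lineages mapped to marker gene symbols."""

    lineages: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKER_PANEL.items()})

    def __post_init__(self) -> None:
        union = self.union
        if len(set(union)) != len(union):
            seen, dup = set(), set()
            for g in union:
                (dup if g in seen else seen).add(g)
            raise ValueError(f"marker symbols repeated across lineages: {sorted(dup)}")

    @property
    def union(self) -> list[str]:
        out: list[str] = []
        for genes in self.lineages.values():
            out.extend(genes)
        return out

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanel":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls({str(k): [str(g) for g in v] for k, v in data.items()})


@dataclass
class NicheConfig:
    score_threshold: float = 0.9  # strict >
    min_marker_coverage: float = 0.5  # fraction of panel genes required in matrix

    def __post_init__(self) -> None:
        if not np.isfinite(self.score_threshold):
            raise ValueError("score_threshold must be finite")
        if not (0 < self.min_marker_coverage <= 1):
            raise ValueError("min_marker_coverage must be in (0, 1]")


@dataclass
class NicheLabels:
    """Per-spot niche class (immune / adjacent / away) with stratum and score."""

    table: pd.DataFrame  # index barcode; columns label, stratum, score

    def counts(self) -> dict:
        c = self.table["label"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("immune", "adjacent", "away")}

    def counts_by_stratum(self) -> dict:
        out: dict = {}
        for (lab, strat), n in self.table.groupby(["label", "stratum"], observed=True).size().items():
            out[f"{strat}_{lab}"] = int(n)
        return out

    def spots(self, label: str, stratum: str | None = None) -> pd.Index:
        mask = self.table["label"] == label
        if stratum is not None:
            mask &= self.table["stratum"] == stratum
        return self.table.index[mask]


def marker_score(nm: NormalizedMatrix, panel: MarkerPanel | dict | None = None,
                 cfg: NicheConfig | None = None) -> pd.Series:
    """Mean log-normalized expression over the panel union, per spot.

    Panel genes absent from the matrix are dropped from the denominator (and
    logged); if fewer than ``min_marker_coverage`` of the panel remain, an
    error lists the missing symbols.
    """
    if panel is None:
        panel = MarkerPanel()
    elif isinstance(panel, dict):
        panel = MarkerPanel(panel)
    cfg = cfg or NicheConfig()
    union = panel.union
    gene_pos = pd.Index(nm.genes)
    present = [g for g in union if g in gene_pos]
    missing = [g for g in union if g not in gene_pos]
    if len(present) < cfg.min_marker_coverage * len(union):
        raise ValueError(
            f"only {len(present)}/{len(union)} marker genes present "
            f"(need >= {cfg.min_marker_coverage:.0%}); missing: {missing}"
        )
    if missing:
        logger.info("marker panel: %d/%d genes absent, denominator is %d: %s",
                    len(missing), len(union), len(present), missing)
    rows = gene_pos.get_indexer(present)
    scores = np.asarray(nm.matrix[rows, :].mean(axis=0)).ravel()
    return pd.Series(scores, index=pd.Index(nm.spots, name="barcode"), name="marker_score")


def call_immune_spots(scores: pd.Series, cfg: NicheConfig | None = None) -> set:
    """Spots whose marker score strictly exceeds the threshold."""
    cfg = cfg or NicheConfig()
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite marker scores")
    return set(scores.index[s > cfg.score_threshold])


def hex_neighbors(grid: SpotGrid, spot_id: str) -> set:
    """The <= 6 same-slide spots in hex contact with *spot_id*."""
    t = grid.table
    if spot_id not in t.index:
        raise KeyError(f"unknown spot {spot_id!r}")
    slide = t.at[spot_id, "slide_id"]
    r = int(t.at[spot_id, "array_row"])
    c = int(t.at[spot_id, "array_col"])
    out = set()
    for dr, dc in HEX_OFFSETS:
        nb = grid.spot_at(slide, r + dr, c + dc)
        if nb is not None:
            out.add(nb)
    return out


def _adjacency_to(grid: SpotGrid, sources: set) -> set:
    """All spots with >= 1 hex neighbor inside *sources* (may include sources)."""
    touched = set()
    for s in sources:
        touched |= hex_neighbors(grid, s)
    return touched


def classify_niche(grid: SpotGrid, immune: set, scores: pd.Series | None = None) -> NicheLabels:
    """Partition analyzed spots into immune / adjacent / away.

    Precedence immune > adjacent: an immune spot next to another immune spot
    stays immune.  Stratum is copied from the grid's region label.
    """
    analyzed = grid.analyzed
    unknown = set(immune) - set(grid.barcodes)
    if unknown:
        raise KeyError(f"immune set contains spots not in grid: {sorted(unknown)[:5]}")
    immune_set = set(immune) & set(analyzed)
    touched = _adjacency_to(grid, immune_set)
    labels = []
    for b in analyzed:
        if b in immune_set:
            labels.append("immune")
        elif b in touched:
            labels.append("adjacent")
        else:
            labels.append("away")
    table = pd.DataFrame(
        {
            "label": labels,
            "stratum": grid.table.loc[analyzed, "region"].to_numpy(),
            "score": (scores.reindex(analyzed).to_numpy() if scores is not None else np.nan),
        },
        index=pd.Index(analyzed, name="barcode"),
    )
    return NicheLabels(table)


@dataclass
class Contrast:
    """Two disjoint spot groups to compare (group1 vs group2)."""

    name: str
    group1: list
    group2: list

    def __post_init__(self) -> None:
        if set(self.group1) & set(self.group2):
            raise ValueError(f"contrast {self.name}: groups overlap")


@dataclass
class ContrastSet:
    contrasts: dict[str, Contrast]
    failures: dict[str, str]

    def __getitem__(self, name: str) -> Contrast:
        if name in self.failures:
            raise ValueError(f"contrast {name!r} unavailable: {self.failures[name]}")
        return self.contrasts[name]


def build_contrasts(labels: NicheLabels, strict: bool = False) -> ContrastSet:
    """The three region-stratified adjacency contrasts.

    1. tumor adjacent vs tumor away
    2. benign adjacent vs benign away
    3. tumor adjacent vs benign adjacent

    Immune spots never enter any group.  Contrasts with an empty required
    group are reported in ``failures`` (or raised when ``strict``).
    """
    groups = {
        ("tumor", "adjacent"): list(labels.spots("adjacent", "tumor")),
        ("tumor", "away"): list(labels.spots("away", "tumor")),
        ("benign", "adjacent"): list(labels.spots("adjacent", "benign")),
        ("benign", "away"): list(labels.spots("away", "benign")),
    }
    defs = {
        "tumor_adjacent_vs_away": (("tumor", "adjacent"), ("tumor", "away")),
        "benign_adjacent_vs_away": (("benign", "adjacent"), ("benign", "away")),
        "tumor_adjacent_vs_benign_adjacent": (("tumor", "adjacent"), ("benign", "adjacent")),
    }
    contrasts: dict[str, Contrast] = {}
    failures: dict[str, str] = {}
    for name, (k1, k2) in defs.items():
        g1, g2 = groups[k1], groups[k2]
        empty = [f"{k[0]} {k[1]}" for k, g in ((k1, g1), (k2, g2)) if len(g) == 0]
        if empty:
            msg = f"empty group(s): {', '.join(empty)}"
            if strict:
                raise ValueError(f"contrast {name}: {msg}")
            failures[name] = msg
        else:
            contrasts[name] = Contrast(name, g1, g2)
    return ContrastSet(contrasts, failures)
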