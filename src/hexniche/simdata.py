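"""Synthetic two-slide Visium-like datasets with known ground truth.

The generator emulates the statistical structure of a two-slide Visium run on
a hepatocellular carcinoma case: ~6,300 in-tissue spots on hexagonal lattices
(56 × 56 per slide by default), a contiguous benign band on slide 1, patchy
contiguous tumor subclones, ~4.6% immune cell-enriched spots biased toward
the benign border, planted adjacency-response gene programs that are broader
in tumor than in benign tissue (default 200 vs 67 genes at |log2FC| = 1), and
two sequencing-depth regimes whose mean library sizes differ 35-fold.

Counts are negative-binomial with lognormal library sizes — the standard
overdispersed model for UMI data.  All randomness flows from one integer seed
through derived generator streams; tissue structure (grid, truth, gene
programs) is shared between depth regimes, so depth is the only systematic
difference between a deep and a standard simulation.

Marker calibration: each immune spot receives a target mean marker score on
the log-CP10K scale, drawn as ``immune_marker_lognorm_target`` (a floor that
must exceed the 0.9 calling threshold) plus a right-skewed Gamma excess.  The
floor guarantees near-complete recall at deep depth while the skewed excess
creates the sub-population of strongly enriched spots that survives 35×
thinning — mirroring real tissue, where most immune spots sit far above the
calling threshold and only marginal ones are lost at standard depth.  The
marker rate is solved numerically so the *expected* score under the
negative-binomial sampling at the spot's library size equals the target
(a plain plug-in rate would undershoot by Jensen's inequality).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .niche import DEFAULT_MARKER_PANEL, HEX_OFFSETS
from .spatial_io import CountMatrix, SpotGrid, write_counts, write_positions, write_regions

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_grid",
    "plant_truth",
    "simulate_counts",
    "simulate_composition",
    "write_dataset",
]

DEPTH_REGIMES = ("deep", "standard")

# stream tags for deriving independent generators from the one config seed
_TAG_TRUTH = 1
_TAG_PROGRAMS = 2
_TAG_COUNTS = {"deep": 3, "standard": 4}
_TAG_COMPOSITION = 5


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic dataset; defaults are the study conditions."""

    seed: int = 0
    slides: int = 2
    n_rows: int = 56
    n_cols: int = 56
    benign_fraction_slide1: float = 0.25
    n_subclones: int = 15
    n_genes: int = 5000
    n_marker_genes: int = 23
    immune_spot_fraction: float = 0.046
    immune_benign_bias: float = 3.0
    immune_marker_lognorm_target: float = 1.2
    immune_marker_spread: float = 0.7  # mean of the Gamma excess above the target floor
    n_response_genes_tumor: int = 200
    n_response_genes_benign: int = 67
    response_log2fc: float = 1.0
    nb_dispersion: float = 0.3
    depth_deep_mean: float = 20000.0
    depth_standard_mean: float = 20000.0 / 35.0
    library_sigma: float = 0.35  # sd of log library size

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.slides < 1:
            raise ValueError("need at least one slide")
        if not (0 < self.immune_spot_fraction < 1):
            raise ValueError("immune_spot_fraction must be in (0, 1)")
        if not (0 <= self.benign_fraction_slide1 <= 1):
            raise ValueError("benign_fraction_slide1 must be in [0, 1]")
        if self.depth_deep_mean <= self.depth_standard_mean:
            raise ValueError("depth_deep_mean must exceed depth_standard_mean")
        if self.immune_benign_bias <= 0:
            raise ValueError("immune_benign_bias must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        total_special = self.n_response_genes_tumor + self.n_response_genes_benign + self.n_marker_genes
        if total_special > self.n_genes:
            raise ValueError(
                f"marker + response genes ({total_special}) exceed n_genes ({self.n_genes})"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)

    def marker_symbols(self) -> list[str]:
        union: list[str] = []
        for genes in DEFAULT_MARKER_PANEL.values():
            union.extend(genes)
        if self.n_marker_genes <= len(union):
            return union[: self.n_marker_genes]
        extra = [f"MARKER{i}" for i in range(self.n_marker_genes - len(union))]
        return union + extra

    def gene_symbols(self) -> list[str]:
        markers = self.marker_symbols()
        others = [f"G{i:05d}" for i in range(self.n_genes - len(markers))]
        return markers + others


@dataclass
class GroundTruth:
    """What was planted: immune spots, response genes with signed effects, patches."""

    immune_spot_ids: set
    response_genes_tumor: dict  # gene -> signed log2 fold change
    response_genes_benign: dict
    subclone_assignment: dict  # barcode -> patch id (-1 = benign program)
    marker_targets: dict = field(default_factory=dict)  # immune barcode -> score target

    def to_json(self, path) -> None:
        payload = {
            "immune_spot_ids": sorted(self.immune_spot_ids),
            "response_genes_tumor": self.response_genes_tumor,
            "response_genes_benign": self.response_genes_benign,
            "subclone_assignment": self.subclone_assignment,
            "marker_targets": self.marker_targets,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            immune_spot_ids=set(d["immune_spot_ids"]),
            response_genes_tumor=d["response_genes_tumor"],
            response_genes_benign=d["response_genes_benign"],
            subclone_assignment={k: int(v) for k, v in d["subclone_assignment"].items()},
            marker_targets=d.get("marker_targets", {}),
        )


def _rng(config: SyntheticConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, tag]))


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------


def generate_grid(config: SyntheticConfig) -> SpotGrid:
    """Deterministic hex lattice per slide with the Visium parity convention.

    Slide 1 carries a contiguous benign band of
    ``ceil(benign_fraction_slide1 * n_rows)`` top rows; everything else is
    tumor.  Spots sit at (r, 2j + r mod 2) so row and column share parity.
    """
    rows = []
    n_benign_rows = math.ceil(config.benign_fraction_slide1 * config.n_rows)
    for k in range(1, config.slides + 1):
        slide = f"slide{k}"
        for r in range(config.n_rows):
            for j in range(config.n_cols):
                c = 2 * j + (r % 2)
                region = "benign" if (k == 1 and r < n_benign_rows) else "tumor"
                rows.append((f"s{k}_{r:03d}_{c:03d}", slide, r, c, True, region))
    df = pd.DataFrame(
        rows, columns=["barcode", "slide_id", "array_row", "array_col", "in_tissue", "region"]
    ).set_index("barcode")
    return SpotGrid(df)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def _position_lookup(grid: SpotGrid) -> dict:
    t = grid.table
    return {
        (s, int(r), int(c)): b
        for b, s, r, c in zip(t.index, t["slide_id"], t["array_row"], t["array_col"])
    }


def _neighbors_of(grid: SpotGrid, pos: dict, barcode: str) -> list:
    t = grid.table
    slide = t.at[barcode, "slide_id"]
    r = int(t.at[barcode, "array_row"])
    c = int(t.at[barcode, "array_col"])
    out = []
    for dr, dc in HEX_OFFSETS:
        nb = pos.get((slide, r + dr, c + dc))
        if nb is not None:
            out.append(nb)
    return out


def _ring(grid: SpotGrid, sources: set, steps: int) -> set:
    """All spots within *steps* hex steps of *sources* (including sources)."""
    pos = _position_lookup(grid)
    reached = set(sources)
    frontier = set(sources)
    for _ in range(steps):
        nxt = set()
        for b in frontier:
            nxt.update(_neighbors_of(grid, pos, b))
        nxt -= reached
        reached |= nxt
        frontier = nxt
    return reached


def _grow_patches(grid: SpotGrid, rng: np.random.Generator, n_patches: int) -> dict:
    """Seeded region-growing of contiguous tumor patches on the hex lattice.

    Benign spots get patch id -1.  Seeds are split across slides in proportion
    to each slide's tumor spot count (at least one per slide), so every tumor
    spot is reachable from a same-slide seed.
    """
    pos = _position_lookup(grid)
    t = grid.table
    tumor = t.index[(t["region"] == "tumor") & t["in_tissue"]]
    assignment = {b: -1 for b in t.index[t["region"] == "benign"]}
    slides = sorted(t.loc[tumor, "slide_id"].unique())
    counts = {s: int((t.loc[tumor, "slide_id"] == s).sum()) for s in slides}
    total = sum(counts.values())
    n_patches = min(n_patches, len(tumor))
    seeds_per_slide = {s: max(1, round(n_patches * counts[s] / total)) for s in slides}
    # adjust so totals match n_patches
    while sum(seeds_per_slide.values()) > n_patches:
        s = max(seeds_per_slide, key=seeds_per_slide.get)
        if seeds_per_slide[s] > 1:
            seeds_per_slide[s] -= 1
        else:
            break
    while sum(seeds_per_slide.values()) < n_patches:
        s = max(slides, key=lambda x: counts[x] / seeds_per_slide[x])
        seeds_per_slide[s] += 1

    patch_id = 0
    frontiers: dict[int, list] = {}
    for s in slides:
        cand = list(tumor[t.loc[tumor, "slide_id"] == s])
        picks = rng.choice(len(cand), size=min(seeds_per_slide[s], len(cand)), replace=False)
        for i in picks:
            assignment[cand[i]] = patch_id
            frontiers[patch_id] = [cand[i]]
            patch_id += 1

    unassigned = set(tumor) - set(b for b, p in assignment.items() if p >= 0)
    # randomized multi-source growth: repeatedly expand a random patch frontier
    active = [p for p in frontiers if frontiers[p]]
    while unassigned and active:
        p = active[int(rng.integers(len(active)))]
        new_frontier = []
        grabbed = []
        for b in frontiers[p]:
            for nb in _neighbors_of(grid, pos, b):
                if nb in unassigned:
                    unassigned.discard(nb)
                    assignment[nb] = p
                    grabbed.append(nb)
            if any(nb in unassigned for nb in _neighbors_of(grid, pos, b)):
                new_frontier.append(b)
        frontiers[p] = new_frontier + grabbed
        if not frontiers[p]:
            active.remove(p)
    # lattice components are connected per slide, so nothing should remain
    for b in unassigned:  # pragma: no cover - safety net
        assignment[b] = 0
    return assignment


def plant_truth(grid: SpotGrid, config: SyntheticConfig) -> GroundTruth:
    """Choose immune spots, response gene sets and subclone patches.

    Immune spots are sampled without replacement with weight
    ``immune_benign_bias`` for spots within two hex steps of the benign
    region and weight 1 elsewhere, until ``ceil(immune_spot_fraction * N)``
    spots are chosen.  Response gene sets are disjoint from each other and
    from the marker panel, drawn from genes above the 60th percentile of
    baseline expression weight (see module docstring).
    """
    if set(grid.table["region"]) <= {"unassigned"}:
        raise ValueError("grid has no region labels")
    rng = _rng(config, _TAG_TRUTH)
    analyzed = list(grid.analyzed)
    n_immune = math.ceil(config.immune_spot_fraction * len(analyzed))
    if n_immune > len(analyzed):
        raise ValueError(f"requested {n_immune} immune spots but grid has {len(analyzed)}")

    benign = set(grid.table.index[grid.table["region"] == "benign"])
    near_benign = _ring(grid, benign, steps=2) if benign else set()
    weights = np.array(
        [config.immune_benign_bias if b in near_benign else 1.0 for b in analyzed]
    )
    weights = weights / weights.sum()
    picked = rng.choice(len(analyzed), size=n_immune, replace=False, p=weights)
    immune = {analyzed[i] for i in picked}

    # marker-score targets: floor + right-skewed excess (see module docstring)
    targets = config.immune_marker_lognorm_target + rng.gamma(
        shape=2.0, scale=config.immune_marker_spread / 2.0, size=n_immune
    )
    marker_targets = {b: float(s) for b, s in zip(sorted(immune), targets)}

    # response genes: disjoint draws from expressed non-marker genes
    genes = config.gene_symbols()
    markers = set(config.marker_symbols())
    base_w = _baseline_weights(config)
    w_floor = np.quantile(base_w, 0.60)
    eligible = [g for g, w in zip(genes, base_w) if g not in markers and w >= w_floor]
    n_resp = config.n_response_genes_tumor + config.n_response_genes_benign
    if n_resp > len(eligible):
        raise ValueError("not enough expressed non-marker genes for the response sets")
    picked_g = rng.choice(len(eligible), size=n_resp, replace=False)
    signs = rng.choice([1.0, -1.0], size=n_resp)
    resp = [(eligible[i], float(s * config.response_log2fc)) for i, s in zip(picked_g, signs)]
    tumor_resp = dict(resp[: config.n_response_genes_tumor])
    benign_resp = dict(resp[config.n_response_genes_tumor:])

    assignment = _grow_patches(grid, rng, config.n_subclones)
    return GroundTruth(
        immune_spot_ids=immune,
        response_genes_tumor=tumor_resp,
        response_genes_benign=benign_resp,
        subclone_assignment=assignment,
        marker_targets=marker_targets,
    )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

MARKER_BACKGROUND_WEIGHT = 0.05  # relative baseline weight of marker genes outside immune spots
PATCH_PROGRAM_FRACTION = 0.05
PATCH_PROGRAM_SD = 0.4  # log2 sd of subclone program shifts
BENIGN_PROGRAM_FRACTION = 0.08
BENIGN_PROGRAM_SD = 0.6


def _baseline_weights(config: SyntheticConfig) -> np.ndarray:
    """Per-gene relative expression weights (heavy-tailed lognormal).

    Drawn from the program stream so both depth regimes share them.
    """
    rng = _rng(config, _TAG_PROGRAMS)
    w = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_genes)
    w[: config.n_marker_genes] = MARKER_BACKGROUND_WEIGHT
    return w


def _patch_programs(config: SyntheticConfig, truth: GroundTruth) -> dict:
    """Per-patch multiplicative gene programs (patch id -> multiplier vector)."""
    rng = _rng(config, _TAG_PROGRAMS)
    rng.lognormal(mean=0.0, sigma=1.5, size=config.n_genes)  # skip baseline draw
    genes = config.gene_symbols()
    special = set(config.marker_symbols()) | set(truth.response_genes_tumor) | set(
        truth.response_genes_benign
    )
    eligible = np.array([i for i, g in enumerate(genes) if g not in special])
    patches = sorted(set(truth.subclone_assignment.values()))
    programs = {}
    for p in patches:
        frac = BENIGN_PROGRAM_FRACTION if p == -1 else PATCH_PROGRAM_FRACTION
        sd = BENIGN_PROGRAM_SD if p == -1 else PATCH_PROGRAM_SD
        k = max(1, int(frac * len(eligible)))
        idx = rng.choice(eligible, size=k, replace=False)
        mult = np.ones(config.n_genes)
        mult[idx] = 2.0 ** rng.normal(0.0, sd, size=k)
        programs[p] = mult
    return programs


@lru_cache(maxsize=8)
def _marker_rate_curve(library_size: float, dispersion: float,
                       scale_factor: float = 1e4) -> tuple:
    """Monotone curve lam -> E[ln(1 + sf/L * C)], C ~ NB(mean lam, alpha).

    Used to invert the expected log-CP10K marker score to the underlying
    expected count; cached because it depends only on the reference depth and
    the dispersion.
    """
    factor = scale_factor / library_size
    lam_grid = np.concatenate([[0.0], np.geomspace(1e-3, 4e3, 400)])
    kmax = int(4e3 + 10 * math.sqrt(4e3) + 50)
    k = np.arange(kmax + 1)
    logv = np.log1p(factor * k)
    if dispersion <= 0:
        pmf = scipy.stats.poisson.pmf(k[None, :], np.maximum(lam_grid, 1e-12)[:, None])
    else:
        n = 1.0 / dispersion
        p = n / (n + np.maximum(lam_grid, 1e-12))
        pmf = scipy.stats.nbinom.pmf(k[None, :], n, p[:, None])
    scores = pmf @ logv
    scores[0] = 0.0
    return tuple(lam_grid), tuple(scores)


def _solve_marker_rate(target: float, library_size: float, dispersion: float,
                       scale_factor: float = 1e4) -> float:
    """Expected marker count per gene so the mean log-CP10K score hits *target*."""
    lam_grid, scores = _marker_rate_curve(float(library_size), float(dispersion),
                                          float(scale_factor))
    return float(np.interp(target, np.asarray(scores), np.asarray(lam_grid)))


def simulate_counts(grid: SpotGrid, truth: GroundTruth, config: SyntheticConfig,
                    depth: str = "deep") -> CountMatrix:
    """Negative-binomial counts at a given depth regime.

    Library sizes are lognormal around the regime's target mean; gene rates
    combine baseline weights, subclone programs, planted marker enrichment in
    immune spots and planted adjacency-response shifts in spots hex-adjacent
    to immune spots (tumor-response genes act only in tumor spots,
    benign-response genes only in benign spots).
    """
    if depth not in DEPTH_REGIMES:
        raise ValueError(f"unknown depth regime {depth!r}; expected one of {DEPTH_REGIMES}")
    missing = truth.immune_spot_ids - set(grid.barcodes)
    if missing:
        raise ValueError(f"truth immune spots not in grid: {sorted(missing)[:5]}")
    rng = _rng(config, _TAG_COUNTS[depth])
    analyzed = list(grid.analyzed)
    n_spots = len(analyzed)
    genes = config.gene_symbols()
    n_genes = config.n_genes

    depth_mean = config.depth_deep_mean if depth == "deep" else config.depth_standard_mean
    mu = math.log(depth_mean) - config.library_sigma**2 / 2.0
    libsizes = rng.lognormal(mean=mu, sigma=config.library_sigma, size=n_spots)

    base = _baseline_weights(config)
    programs = _patch_programs(config, truth)
    rates = np.empty((n_genes, n_spots), dtype=np.float64)
    spot_pos = {b: i for i, b in enumerate(analyzed)}
    patch_of = truth.subclone_assignment
    for p, mult in programs.items():
        cols = [spot_pos[b] for b in analyzed if patch_of.get(b, 0) == p]
        if cols:
            rates[:, cols] = (base * mult)[:, None]
    # spots without a patch entry (shouldn't happen) fall back to baseline
    missing_cols = [i for i, b in enumerate(analyzed) if patch_of.get(b) is None]
    if missing_cols:
        rates[:, missing_cols] = base[:, None]

    # planted adjacency-response shifts in non-immune neighbors of immune spots
    adjacent = _ring(grid, truth.immune_spot_ids, steps=1) - truth.immune_spot_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    regions = grid.table["region"]
    adj_tumor = [spot_pos[b] for b in adjacent if b in spot_pos and regions[b] == "tumor"]
    adj_benign = [spot_pos[b] for b in adjacent if b in spot_pos and regions[b] == "benign"]
    for resp, cols in ((truth.response_genes_tumor, adj_tumor),
                       (truth.response_genes_benign, adj_benign)):
        if not cols:
            continue
        for g, lfc in resp.items():
            rates[gene_pos[g], cols] *= 2.0**lfc

    # close columns to relative rates
    rates /= rates.sum(axis=0, keepdims=True)

    # Marker enrichment in immune spots, calibrated on the log-CP10K scale.
    # The marker fraction is a tissue property: it is solved once at the deep
    # reference depth and reused for every regime, so an independently
    # simulated standard run shares the deep run's composition and differs
    # only through sampling depth.
    n_markers = config.n_marker_genes
    for b in sorted(truth.immune_spot_ids):
        i = spot_pos.get(b)
        if i is None:
            continue
        target = truth.marker_targets.get(b, config.immune_marker_lognorm_target)
        lam_ref = _solve_marker_rate(target, config.depth_deep_mean, config.nb_dispersion)
        q = lam_ref / config.depth_deep_mean
        marker_mass = min(n_markers * q, 0.9)
        col = rates[:, i]
        nonmarker_mass = col[n_markers:].sum()
        col[n_markers:] *= (1.0 - marker_mass) / nonmarker_mass
        col[:n_markers] = marker_mass / n_markers

    rates *= libsizes[None, :]
    mean_counts = rates
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mean_counts * config.nb_dispersion)
    else:
        lam = mean_counts
    counts = rng.poisson(lam).astype(np.int32)
    matrix = sp.csr_matrix(counts)
    return CountMatrix(list(genes), analyzed, matrix)


# ---------------------------------------------------------------------------
# composition tables
# ---------------------------------------------------------------------------

N_MACROPHAGE_TYPES = 6


def simulate_composition(factors: pd.DataFrame, depth_effect: float = 0.6,
                         region_effect: float = 0.8, interaction_effect: float = 0.0,
                         concentration: float = 60.0, seed: int = 0):
    """Macrophage-subtype composition per immune spot with planted effects.

    *factors* has one row per observation with columns ``depth`` (deep /
    standard) and ``region`` (tumor / benign).  Baseline logits make subtype 5
    dominant; the depth and region effects shift disjoint subtype pairs on the
    logit scale, and rows are drawn from a Dirichlet around the resulting
    expected composition.  Setting every effect to 0 yields an effect-free
    table for null calibration.
    """
    from .composition import CompositionTable

    if not {"depth", "region"} <= set(factors.columns):
        raise ValueError("factors must have columns depth and region")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _TAG_COMPOSITION]))
    base = np.array([0.0, 0.2, -0.2, 0.0, 1.4, -0.3])  # subtype 5 (index 4) dominant
    rows = np.empty((len(factors), N_MACROPHAGE_TYPES))
    for i, (_, row) in enumerate(factors.iterrows()):
        logits = base.copy()
        if row["depth"] == "deep":
            logits[0] += depth_effect
            logits[1] -= depth_effect
        if row["region"] == "tumor":
            logits[2] += region_effect
            logits[5] -= region_effect
        if row["depth"] == "deep" and row["region"] == "tumor":
            logits[3] += interaction_effect
        pi = np.exp(logits)
        pi /= pi.sum()
        rows[i] = rng.dirichlet(concentration * pi)
    props = pd.DataFrame(
        rows,
        index=factors.index,
        columns=[f"macrophage_type_{k}" for k in range(1, N_MACROPHAGE_TYPES + 1)],
    )
    return CompositionTable(props, factors[["depth", "region"]].copy())


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------


def write_dataset(outdir, grid: SpotGrid, truth: GroundTruth,
                  counts: dict[str, CountMatrix]) -> dict:
    """Write grid, regions, truth and one count triplet per depth regime."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    write_positions(grid, os.path.join(outdir, "tissue_positions.csv"))
    write_regions(grid, os.path.join(outdir, "regions.csv"))
    truth.to_json(os.path.join(outdir, "truth.json"))
    paths["positions"] = os.path.join(outdir, "tissue_positions.csv")
    paths["regions"] = os.path.join(outdir, "regions.csv")
    paths["truth"] = os.path.join(outdir, "truth.json")
    for regime, m in counts.items():
        d = os.path.join(outdir, f"counts_{regime}")
        write_counts(m, d)
        paths[f"counts_{regime}"] = d
    return paths
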