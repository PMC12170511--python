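"""End-to-end orchestration: simulate or load, call niches at two depths,
run the three region-stratified contrasts, compare depths, and test the
myeloid composition — producing a machine-readable report plus flat-file
artifacts under one output directory.

A pipeline run is fully determined by its config: one integer seed derives
every stage's generator stream, and two runs with the same config produce
bit-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .composition import clr_transform, permanova
from .depth import detection_delta, match_genes, thin_counts
from .diffexpr import DEConfig, compare_gene_sets, de_analysis, screen_with_hvg, significant_genes
from .niche import (
    CONTRAST_NAMES,
    MarkerPanel,
    NicheConfig,
    build_contrasts,
    call_immune_spots,
    classify_niche,
    marker_score,
)
from .preprocess import detection_rates, normalize, select_hvg
from .simdata import SyntheticConfig, generate_grid, plant_truth, simulate_counts, simulate_composition, write_dataset
from .spatial_io import read_counts, read_positions, write_labels

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

logger = logging.getLogger(__name__)

# fixed offsets deriving stage seeds from the one config seed
_SEED_THIN = 101
_SEED_PERMANOVA = 202
_SEED_COMPOSITION = 303


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of *simulate* / *inputs* is set."""

    outdir: str = "hexniche_out"
    simulate: SyntheticConfig | None = None
    inputs: dict | None = None  # counts_deep, positions[, counts_standard, regions]
    niche: NicheConfig = field(default_factory=NicheConfig)
    de: DEConfig = field(default_factory=DEConfig)
    panel: MarkerPanel = field(default_factory=MarkerPanel)
    hvg_n: int = 3000
    standard_mode: str = "thin"  # thin deep counts, or "simulate"/"load" a second run
    thin_rate: float | None = None  # default: depth_standard_mean / depth_deep_mean
    composition_enabled: bool = True
    composition_depth_effect: float = 0.6
    composition_region_effect: float = 0.8
    composition_interaction_effect: float = 0.0
    composition_n_perm: int = 999
    log_level: str = "INFO"
    write_files: bool = True

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must set exactly one of simulate / inputs")
        if self.inputs is not None:
            missing = {"counts_deep", "positions"} - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block missing keys: {sorted(missing)}")
        if self.standard_mode not in ("thin", "simulate", "load"):
            raise ValueError("standard_mode must be thin, simulate or load")

    @property
    def seed(self) -> int:
        return self.simulate.seed if self.simulate is not None else 0

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "simulate": None if self.simulate is None else self.simulate.to_dict(),
            "inputs": self.inputs,
            "niche": {"score_threshold": self.niche.score_threshold,
                      "min_marker_coverage": self.niche.min_marker_coverage},
            "de": {"min_pct": self.de.min_pct, "lfc_min": self.de.lfc_min,
                   "alpha": self.de.alpha, "pseudocount": self.de.pseudocount},
            "panel": self.panel.lineages,
            "hvg_n": self.hvg_n,
            "standard_mode": self.standard_mode,
            "thin_rate": self.thin_rate,
            "composition": {
                "enabled": self.composition_enabled,
                "depth_effect": self.composition_depth_effect,
                "region_effect": self.composition_region_effect,
                "interaction_effect": self.composition_interaction_effect,
                "n_perm": self.composition_n_perm,
            },
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw: dict = {}
        if "simulate" in raw and raw["simulate"] is not None:
            kw["simulate"] = SyntheticConfig.from_dict(raw["simulate"])
        if raw.get("inputs") is not None:
            kw["inputs"] = dict(raw["inputs"])
        if "niche" in raw:
            kw["niche"] = NicheConfig(**raw["niche"])
        if "de" in raw:
            kw["de"] = DEConfig(**raw["de"])
        if "panel" in raw:
            kw["panel"] = MarkerPanel(raw["panel"])
        comp = raw.get("composition", {})
        for key, attr in (("enabled", "composition_enabled"),
                          ("depth_effect", "composition_depth_effect"),
                          ("region_effect", "composition_region_effect"),
                          ("interaction_effect", "composition_interaction_effect"),
                          ("n_perm", "composition_n_perm")):
            if key in comp:
                kw[attr] = comp[key]
        for key in ("outdir", "hvg_n", "standard_mode", "thin_rate", "log_level"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # analysis identity, not output location
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _analyze_regime(name, counts, grid, cfg: PipelineConfig, outdir=None):
    """Niche calling + the three contrasts for one depth regime."""
    spots = [s for s in counts.spots if s in set(grid.analyzed)]
    m = counts.subset_spots(spots) if len(spots) != len(counts.spots) else counts
    nm = normalize(m)
    scores = marker_score(nm, cfg.panel, cfg.niche)
    immune = call_immune_spots(scores, cfg.niche)
    labels = classify_niche(grid, immune, scores)
    contrasts = build_contrasts(labels, strict=False)
    hvg = select_hvg(m, n=cfg.hvg_n)
    de_tables: dict[str, pd.DataFrame] = {}
    for cname in CONTRAST_NAMES:
        if cname in contrasts.contrasts:
            de_tables[cname] = de_analysis(nm, contrasts.contrasts[cname], cfg.de)
    if outdir is not None:
        write_labels(labels.table, os.path.join(outdir, f"niche_labels_{name}.csv"))
        for cname, table in de_tables.items():
            table.to_csv(os.path.join(outdir, f"de_{cname}_{name}.tsv"), sep="\t")
        pd.DataFrame({"gene": hvg, "rank": range(1, len(hvg) + 1)}).to_csv(
            os.path.join(outdir, f"hvg_{name}.tsv"), sep="\t", index=False
        )
    return {
        "matrix": m,
        "labels": labels,
        "immune": immune,
        "contrast_failures": contrasts.failures,
        "de": de_tables,
        "hvg": hvg,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and return the report dict."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    t0 = time.time()
    outdir = cfg.outdir if cfg.write_files else None
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    # --- stage: acquire data --------------------------------------------------
    truth = None
    if cfg.simulate is not None:
        sim = cfg.simulate
        grid = generate_grid(sim)
        truth = plant_truth(grid, sim)
        counts_deep = simulate_counts(grid, truth, sim, depth="deep")
        thin_rate = cfg.thin_rate or sim.depth_standard_mean / sim.depth_deep_mean
        if cfg.standard_mode == "simulate":
            counts_standard = simulate_counts(grid, truth, sim, depth="standard")
        else:
            counts_standard = thin_counts(counts_deep, rate=thin_rate,
                                          seed=(sim.seed + _SEED_THIN) & 0x7FFFFFFF)
        if outdir:
            write_dataset(os.path.join(outdir, "synthetic"), grid, truth,
                          {"deep": counts_deep, "standard": counts_standard})
    else:
        inp = cfg.inputs
        grid = read_positions(inp["positions"], inp.get("regions"))
        d = inp["counts_deep"]
        counts_deep = read_counts(os.path.join(d, "matrix.mtx"),
                                  os.path.join(d, "features.tsv"),
                                  os.path.join(d, "barcodes.tsv"))
        if cfg.standard_mode == "load":
            if "counts_standard" not in inp:
                raise ValueError("standard_mode=load requires inputs.counts_standard")
            d = inp["counts_standard"]
            counts_standard = read_counts(os.path.join(d, "matrix.mtx"),
                                          os.path.join(d, "features.tsv"),
                                          os.path.join(d, "barcodes.tsv"))
        else:
            thin_rate = cfg.thin_rate or 1.0 / 35.0
            counts_standard = thin_counts(counts_deep, rate=thin_rate, seed=_SEED_THIN)
    logger.info("data: %d spots, %d genes", len(grid.analyzed), len(counts_deep.genes))

    # --- stage: per-regime niche + DE -----------------------------------------
    regimes = {}
    for name, m in (("deep", counts_deep), ("standard", counts_standard)):
        try:
            regimes[name] = _analyze_regime(name, m, grid, cfg, outdir)
        except Exception as e:  # propagate with the stage name
            raise RuntimeError(f"stage niche/de ({name} regime) failed: {e}") from e
        logger.info("%s regime: %s", name, regimes[name]["labels"].counts())

    # --- stage: depth comparison ----------------------------------------------
    det_deep = detection_rates(regimes["deep"]["matrix"])
    det_std = detection_rates(regimes["standard"]["matrix"])
    matched, _, _ = match_genes(det_deep, det_std)
    comparison = detection_delta(det_deep, det_std, matched)
    if outdir:
        comparison.per_gene.to_csv(os.path.join(outdir, "depth_comparison.tsv"), sep="\t")

    # --- stage: gene-set overlaps ---------------------------------------------
    overlaps = {}
    for cname in CONTRAST_NAMES:
        deep_tab = regimes["deep"]["de"].get(cname)
        std_tab = regimes["standard"]["de"].get(cname)
        if deep_tab is None or std_tab is None:
            continue
        comp = compare_gene_sets(significant_genes(deep_tab), significant_genes(std_tab))
        overlaps[cname] = comp.counts
        if outdir:
            with open(os.path.join(outdir, f"overlap_{cname}.json"), "w") as fh:
                json.dump(comp.to_dict(), fh, indent=1, sort_keys=True)

    # --- stage: composition PERMANOVA -----------------------------------------
    composition_result: dict = {"enabled": cfg.composition_enabled}
    if cfg.composition_enabled:
        obs = []
        for name in ("deep", "standard"):
            lab = regimes[name]["labels"].table
            imm = lab[(lab["label"] == "immune") & lab["stratum"].isin(["tumor", "benign"])]
            for b, row in imm.iterrows():
                obs.append({"obs": f"{name}:{b}", "depth": name, "region": row["stratum"]})
        factors = pd.DataFrame(obs).set_index("obs") if obs else pd.DataFrame()
        feasible = (
            len(factors) >= 8
            and factors.get("depth") is not None
            and factors["depth"].nunique() == 2
            and factors["region"].nunique() == 2
            and pd.crosstab(factors["depth"], factors["region"]).to_numpy().min() >= 2
        )
        if feasible:
            table = simulate_composition(
                factors,
                depth_effect=cfg.composition_depth_effect,
                region_effect=cfg.composition_region_effect,
                interaction_effect=cfg.composition_interaction_effect,
                seed=(cfg.seed + _SEED_COMPOSITION) & 0x7FFFFFFF,
            )
            clr = clr_transform(table)
            result = permanova(clr, table.factors["depth"], table.factors["region"],
                               n_perm=cfg.composition_n_perm,
                               seed=(cfg.seed + _SEED_PERMANOVA) & 0x7FFFFFFF)
            composition_result.update(result.to_dict())
            composition_result["n_observations"] = len(factors)
            if outdir:
                table.to_csv(os.path.join(outdir, "composition.csv"))
        else:
            composition_result["skipped"] = "design infeasible (need both depths and both regions, >=2 obs per cell)"

    # --- assemble report -------------------------------------------------------
    report = {
        "provenance": {
            "version": _version,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
        },
        "spots": {
            "total_analyzed": int(len(regimes["deep"]["matrix"].spots)),
            "benign": int((grid.table.loc[grid.analyzed, "region"] == "benign").sum()),
            "tumor": int((grid.table.loc[grid.analyzed, "region"] == "tumor").sum()),
        },
        "niche": {
            name: {**regimes[name]["labels"].counts(),
                   **regimes[name]["labels"].counts_by_stratum()}
            for name in ("deep", "standard")
        },
        "diffexpr": {
            name: {
                cname: {
                    "n_significant": int(tab["significant"].sum()),
                    "n_tested": int(tab["tested"].sum()),
                    "n_screened_hvg": len(
                        screen_with_hvg(significant_genes(tab), regimes[name]["hvg"])
                    ),
                }
                for cname, tab in regimes[name]["de"].items()
            }
            for name in ("deep", "standard")
        },
        "contrast_failures": {
            name: regimes[name]["contrast_failures"] for name in ("deep", "standard")
        },
        "depth": comparison.summary(),
        "overlaps": overlaps,
        "composition": composition_result,
    }
    if truth is not None:
        recalled = len(truth.immune_spot_ids & regimes["deep"]["immune"])
        report["truth_recovery"] = {
            "n_true_immune": len(truth.immune_spot_ids),
            "immune_recall_deep": recalled / max(1, len(truth.immune_spot_ids)),
            "immune_false_positives_deep": len(
                regimes["deep"]["immune"] - truth.immune_spot_ids
            ),
        }
    partial = {n: f for n, f in report["contrast_failures"].items() if f}
    report["partial"] = bool(partial)
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    if outdir:
        write_report(report, os.path.join(outdir, "report.json"))
    return report


def write_report(report: dict, path) -> None:
    """JSON with stable key order plus a human-readable summary alongside."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    lines = ["hexniche report", "================", ""]
    spots = report.get("spots", {})
    lines.append(f"analyzed spots: {spots.get('total_analyzed')} "
                 f"(tumor {spots.get('tumor')}, benign {spots.get('benign')})")
    for name in ("deep", "standard"):
        n = report.get("niche", {}).get(name, {})
        lines.append(f"[{name}] immune {n.get('immune')}, adjacent {n.get('adjacent')}, "
                     f"away {n.get('away')}")
        for cname, d in report.get("diffexpr", {}).get(name, {}).items():
            lines.append(f"    {cname}: {d['n_significant']} significant "
                         f"({d['n_screened_hvg']} also highly variable)")
    depth = report.get("depth", {})
    if depth:
        lines.append(
            f"detection: {depth.get('n_increased_in_deep')}/{depth.get('n_genes_matched')} "
            f"genes ({100 * depth.get('fraction_increased', 0):.0f}%) higher at deep depth; "
            f"KS D = {depth.get('ks_D', float('nan')):.3f}"
        )
    comp = report.get("composition", {})
    for term in ("factor_a", "factor_b", "interaction"):
        if term in comp:
            label = {"factor_a": "depth", "factor_b": "region", "interaction": "depth x region"}[term]
            lines.append(f"PERMANOVA {label}: p = {comp[term]['p_value']}")
    with open(os.path.splitext(path)[0] + ".txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")
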