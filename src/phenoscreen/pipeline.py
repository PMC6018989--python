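"""End-to-end orchestration of the screen analysis.

A :class:`RunConfig` names the inputs (either an on-disk screen —
cells.csv + growth.csv — or a synthetic-screen recipe), the WT
replicate ids and the stage thresholds.  :func:`run_pipeline` executes
the stages in dependency order — growth fits, strain features, plate
correction, WT-referenced scores, phenotype flags, consensus islands,
island phenoprints, optional categorical/spatial enrichment, and the
feature network — writing every table plus a JSON manifest carrying
the config hash and seed into the run directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import io as psio
from . import islands as isl
from . import network as net
from . import phenotyping as ph
from . import synthetic as syn
from .growth import fit_gompertz

__all__ = ["RunConfig", "run_pipeline"]

#: the screened non-collinear feature set used for the network stage
NETWORK_FEATURES = [
    "<L>", "<W>", "<A>", "<NA>", "alpha_max", "od_max",
    "rel_T_nuc", "rel_T_const", "rhoCD", "CDN_C0",
]


@dataclass
class RunConfig:
    out_dir: str
    cells_path: str | None = None
    growth_path: str | None = None
    annotations_path: str | None = None
    wt_ids: list[str] | None = None  # inferred from truth for synthetic runs
    synthetic: dict | None = None  # kwargs for synthetic.make_island_truth
    seed: int = 0
    score_threshold: float = 3.0
    constriction_threshold: float = 0.15
    eps: float | None = 4.9
    eps_grid: tuple[float, ...] = (2.0, 3.0, 4.0, 4.9, 6.0)
    min_points: int = 3
    co_threshold: float = 0.9
    n_maps: int = 100
    perplexity: float = 30.0
    n_boot: int = 200
    support_threshold: float = 0.7
    run_islands: bool = True
    run_network: bool = True
    run_enrichment: bool = True

    def validate(self) -> None:
        if self.synthetic is None and (self.cells_path is None or self.growth_path is None):
            raise ValueError("config needs either a synthetic recipe or cells/growth paths")
        for p in (self.cells_path, self.growth_path, self.annotations_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not 0 <= self.co_threshold <= 1 or not 0 <= self.support_threshold <= 1:
            raise ValueError("thresholds must lie in [0, 1]")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": []}

    # ------------------------------------------------------------ inputs
    if config.synthetic is not None:
        truth = syn.make_island_truth(seed=config.seed, **config.synthetic)
        cells, curves, truth = syn.generate_screen(truth)
        wt_ids = sorted(truth.wt_ids)
        psio.write_cells(cells, out / "cells.csv")
        psio.write_growth(curves, out / "growth.csv")
        psio.write_truth(truth, out / "truth.json")
        island_truth = truth.island_labels()
    else:
        cells = psio.read_cells(config.cells_path)
        curves = psio.read_growth(config.growth_path)
        wt_ids = list(config.wt_ids or [])
        island_truth = None
    if not wt_ids:
        raise ValueError("no WT replicates: scores are undefined without a WT reference")
    manifest["stages"].append("inputs")

    # ------------------------------------------------------- growth fits
    fits = {sid: fit_gompertz(c) for sid, c in curves.items()}
    pd.DataFrame(
        [
            {"strain_id": s, "alpha_max": f.alpha_max, "od_max": f.od_max,
             "lag": f.lag, "converged": f.converged}
            for s, f in fits.items()
        ]
    ).to_csv(out / "growthfits.csv", index=False)
    manifest["stages"].append("growth")

    # ---------------------------------------------------------- features
    feats = ph.features_table(cells, fits, config.constriction_threshold)
    low_n = feats.pop("low_n")
    plate_map = {sid: tab["plate"].iloc[0] for sid, tab in cells.items()}
    parental = feats.loc[[w for w in wt_ids if w in feats.index]].median()
    feats = ph.correct_plate_bias(feats, plate_map, parental)
    feats.assign(low_n=low_n).to_csv(out / "features.csv")
    manifest["stages"].append("features")

    # ------------------------------------------------------------ scores
    score_mat = ph.compute_scores(feats, wt_ids)
    scores = score_mat.scores
    scores.to_csv(out / "scores.csv")
    flags = ph.flag_phenotypes(score_mat, config.score_threshold,
                               exclude=set(wt_ids))
    flag_counts = {
        cls: ph.flag_phenotypes(score_mat, config.score_threshold, cls,
                                exclude=set(wt_ids))["count"]
        for cls in ph.FEATURE_CLASSES
    }
    manifest["flagged_strains"] = flags["count"]
    manifest["flagged_by_class"] = flag_counts
    manifest["stages"].append("scores")

    result = {
        "features": feats, "scores": score_mat, "fits": fits,
        "flags": flags, "manifest": manifest, "out_dir": str(out),
        "island_truth": island_truth,
    }

    # ----------------------------------------------------------- islands
    usable = scores.dropna(axis=1, how="any")
    partition = None
    if config.run_islands:
        embeds = isl.embed_consensus(
            usable, n_maps=config.n_maps, perplexity=config.perplexity,
            seed=_stage_seed(config.seed, "islands"),
        )
        if config.eps is None:
            eps, _ = isl.tune_dbscan(embeds, wt_ids, config.eps_grid,
                                     config.min_points, co_threshold=config.co_threshold)
        else:
            eps = config.eps
        partition = isl.consensus_islands(embeds, eps, config.min_points, config.co_threshold)
        part = partition.as_series()
        co_mean = pd.Series(partition.co_matrix.mean(axis=1), index=partition.strain_ids)
        pd.DataFrame({"island_id": part, "co_membership_score": co_mean}).rename_axis(
            "strain_id"
        ).to_csv(out / "islands.csv")
        isl.island_phenoprints(partition, usable).to_csv(out / "island_phenoprints.csv")
        manifest["eps"] = eps
        manifest["n_islands"] = partition.n_islands
        manifest["stages"].append("islands")
        result["partition"] = partition
        result["embeddings"] = embeds

    # -------------------------------------------------------- enrichment
    if config.run_enrichment and config.annotations_path is not None:
        ann = enr.AnnotationMap.read_tsv(config.annotations_path)
        universe = [s for s in scores.index]
        table = enr.term_enrichment(sorted(flags["strains"]), universe, ann, adjust="bh")
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"].append("enrichment")
        result["enrichment"] = table

    # ----------------------------------------------------------- network
    if config.run_network:
        cols = [c for c in NETWORK_FEATURES if c in usable.columns]
        screened = net.belsley_screen(usable[cols])
        pheno_net = net.bootstrap_network(
            usable[screened.retained], n_boot=config.n_boot,
            support_threshold=config.support_threshold,
            seed=_stage_seed(config.seed, "network"),
        )
        pheno_net.write_edges_csv(out / "edges.csv")
        pheno_net.write_graphml(out / "network.graphml")
        manifest["network_edges"] = int(len(pheno_net.edges))
        manifest["stages"].append("network")
        result["network"] = pheno_net

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return result
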