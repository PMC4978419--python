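"""End-to-end orchestration: profile -> cluster -> space -> trajectory.

A single :class:`PipelineConfig` drives every stage with explicit seeds.
One global seed fans out deterministically to per-stage seeds (via
``numpy.random.SeedSequence``), so any stage can be rerun in isolation and
two runs with the same config produce byte-identical numeric outputs.  All
tabular outputs are CSV with stable columns; polytopes and summary
statistics are JSON; the run manifest records config, package versions,
derived seeds and timings.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .profile_compare import (
    class_composition_null,
    distance_matrix,
    hierarchical_cluster_bootstrap,
    kmedoids_select_k,
)
from .sampler import SamplerConfig, generate_network_corpus
from .spectral import spectral_profile
from .synthetic import planted_type_corpus
from .trajectory import trajectory_regressions, trajectory_through_space
from .treespace import (
    fit_polytope,
    map_points,
    t_ratio_test,
    tradeoff_regressions,
    type_hulls,
    volume_stats,
)
from .tree_io import NewickParseError, read_newick_file, tree_metrics, write_newick

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_synthetic_study"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending tree label."""


@dataclass
class PipelineConfig:
    """Configuration for a full run; every stochastic stage has a seed."""

    out_dir: str = "phylospace_out"
    tree_dir: Optional[str] = None  # directory of .nwk files + meta.csv
    meta_csv: Optional[str] = None
    seed: int = 0
    grid_size: int = 512
    k_min: int = 2
    k_max: int = 10
    bootstrap_B: int = 200
    n_perm: int = 200
    polytope_k_max: int = 6
    run_sampler: bool = True
    sampler_n_trees: int = 100
    sampler_nodes: tuple = (20, 100)
    run_rarefaction: bool = False
    composition_iters: int = 500

    def stage_seeds(self) -> dict:
        names = ["cluster", "bootstrap", "space", "sampler", "trajectory", "composition"]
        state = np.random.SeedSequence(self.seed).generate_state(len(names))
        return {n: int(s % 2**31) for n, s in zip(names, state)}


def _load_trees(cfg: PipelineConfig):
    tree_dir = Path(cfg.tree_dir)
    meta_path = Path(cfg.meta_csv) if cfg.meta_csv else tree_dir / "meta.csv"
    meta = pd.read_csv(meta_path)
    trees = []
    for _, row in meta.iterrows():
        path = tree_dir / row["newick_path"]
        try:
            t = read_newick_file(
                path,
                family=row.get("family"),
                taxon_class=row.get("class"),
                sampling_fraction=row.get("sampling_fraction"),
                label=row.get("family"),
            )
        except NewickParseError as exc:
            raise PipelineError(
                f"stage=load tree={row.get('family', path.name)}: {exc}"
            ) from None
        trees.append(t)
    return trees, meta


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write stage outputs plus a run manifest.

    Returns a dict of in-memory stage results (profiles table, clustering,
    polytope fit, trajectory, paths of written files).
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = cfg.stage_seeds()
    timings = {}

    if cfg.tree_dir is None:
        raise PipelineError("stage=load: no tree_dir configured")
    trees, meta = _load_trees(cfg)
    timings["load"] = time.time() - t0

    # -- profiles
    t1 = time.time()
    profiles = []
    for tr in trees:
        try:
            profiles.append(spectral_profile(tr, grid_size=cfg.grid_size))
        except Exception as exc:
            raise PipelineError(f"stage=profile tree={tr.label}: {exc}") from None
    prof_df = pd.DataFrame(
        {
            "label": [p.label for p in profiles],
            "family": [p.family for p in profiles],
            "class": [p.taxon_class for p in profiles],
            "n_tips": [p.n_tips for p in profiles],
            "crown_age": [p.crown_age for p in profiles],
            "lambda_star": [p.lambda_star for p in profiles],
            "psi": [p.psi for p in profiles],
            "eta": [p.eta for p in profiles],
            "modality": [p.modality for p in profiles],
        }
    )
    prof_df.to_csv(out / "profiles.csv", index=False)
    timings["profile"] = time.time() - t1

    # -- clustering
    t1 = time.time()
    dm = distance_matrix(profiles, grid_size=cfg.grid_size)
    clustering = kmedoids_select_k(
        dm, range(cfg.k_min, cfg.k_max + 1), seed=seeds["cluster"]
    )
    dendro = hierarchical_cluster_bootstrap(
        profiles, B=cfg.bootstrap_B, seed=seeds["bootstrap"], grid_size=cfg.grid_size
    )
    clus_df = pd.DataFrame(
        {
            "label": clustering.labels,
            "cluster": clustering.assignments,
            "silhouette": (
                clustering.silhouettes
                if clustering.silhouettes is not None
                else np.full(dm.n, np.nan)
            ),
        }
    )
    clus_df.to_csv(out / "clusters.csv", index=False)
    composition = None
    if meta is not None and "class" in meta.columns:
        classes = dict(zip(prof_df["label"], prof_df["class"]))
        composition = class_composition_null(
            clustering.assignment_map(),
            classes,
            n_iter=cfg.composition_iters,
            seed=seeds["composition"],
        )
        composition.to_csv(out / "composition.csv", index=False)
    timings["cluster"] = time.time() - t1

    # -- space
    t1 = time.time()
    points = map_points(profiles)
    points["cluster"] = clustering.assignments
    points.to_csv(out / "points.csv", index=False)
    poly = fit_polytope(points, k_max=cfg.polytope_k_max, seed=seeds["space"])
    tr_test = t_ratio_test(points, k=3, n_perm=cfg.n_perm, seed=seeds["space"])
    tradeoffs = tradeoff_regressions(points)
    pd.DataFrame([dataclasses.asdict(r) for r in tradeoffs]).to_csv(
        out / "tradeoffs.csv", index=False
    )
    poly_doc = {
        "k": poly.k,
        "vertices_normalized": poly.vertices.tolist(),
        "vertices_raw": poly.vertices_raw.tolist(),
        "explained_variance": {str(k): v for k, v in poly.explained_variance.items()},
        "contributions_pct": poly.contributions.tolist(),
        "t_ratio": tr_test["t_ratio"],
        "t_ratio_p": tr_test["p_value"],
    }
    space_stats = None
    networks = None
    if cfg.run_sampler:
        scfg = SamplerConfig(
            n_nodes_range=cfg.sampler_nodes,
            target_lambda_star_pool=points["lambda_star"].to_numpy(),
            n_trees=cfg.sampler_n_trees,
            seed=seeds["sampler"],
        )
        networks = generate_network_corpus(scfg)
        net_points = map_points([p for _, p in networks])
        net_points.to_csv(out / "network_points.csv", index=False)
        space_stats = volume_stats(points, net_points)
        poly_doc["occupancy_pct_vs_networks"] = space_stats["occupancy_pct"]
        poly_doc["overlap_pct_vs_networks"] = space_stats["overlap_pct"]
    with open(out / "polytope.json", "w") as fh:
        json.dump(poly_doc, fh, indent=2)
    timings["space"] = time.time() - t1

    # -- trajectory
    t1 = time.time()
    hulls = type_hulls(points, clustering.assignments)
    ages = prof_df["crown_age"].to_numpy()
    bins = trajectory_through_space(points, ages, hulls)
    bins.table.to_csv(out / "trajectory.csv", index=False)
    traj_fits = trajectory_regressions(points, ages)
    pd.DataFrame([dataclasses.asdict(r) for r in traj_fits]).to_csv(
        out / "trajectory_fits.csv", index=False
    )
    timings["trajectory"] = time.time() - t1

    manifest = {
        "package": "phylospace",
        "version": __version__,
        "numpy": np.__version__,
        "config": dataclasses.asdict(cfg),
        "stage_seeds": seeds,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_trees": len(trees),
        "selected_k": clustering.k,
        "mean_silhouette": clustering.mean_silhouette,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "profiles": profiles,
        "profiles_table": prof_df,
        "clustering": clustering,
        "dendrogram": dendro,
        "composition": composition,
        "points": points,
        "polytope": poly,
        "t_ratio": tr_test,
        "tradeoffs": tradeoffs,
        "space_stats": space_stats,
        "networks": networks,
        "trajectory": bins,
        "trajectory_fits": traj_fits,
        "manifest": manifest,
        "out_dir": str(out),
    }


#: class labels fabricated for the synthetic study (round-robin over regimes)
SYNTHETIC_CLASSES = ("ClassA", "ClassB", "ClassC", "ClassD", "ClassE")


def make_synthetic_study(
    out_dir: str, seed: int = 0, n_per_type: int = 30
) -> dict:
    """Write a directory mimicking an empirical family-level study layout.

    Trees come from `planted_type_corpus`; the metadata CSV carries
    fabricated family names, round-robin class labels, crown age, sampling
    fraction and the true regime label (ground truth for recovery tests).
    """
    out = Path(out_dir)
    trees_dir = out / "trees"
    trees_dir.mkdir(parents=True, exist_ok=True)
    trees, regimes = planted_type_corpus(n_per_type=n_per_type, seed=seed)
    rows = []
    for i, (tree, regime) in enumerate(zip(trees, regimes)):
        fam = f"fam_{i:03d}"
        fname = f"{fam}.nwk"
        with open(trees_dir / fname, "w") as fh:
            fh.write(write_newick(tree) + "\n")
        m = tree_metrics(tree)
        rows.append(
            {
                "family": fam,
                "class": SYNTHETIC_CLASSES[i % len(SYNTHETIC_CLASSES)],
                "crown_age": m["crown_age"],
                "sampling_fraction": 1.0,
                "newick_path": fname,
                "true_regime": regime,
            }
        )
    meta = pd.DataFrame(rows)
    meta.to_csv(trees_dir / "meta.csv", index=False)
    return {"tree_dir": str(trees_dir), "meta": meta, "trees": trees, "regimes": regimes}
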