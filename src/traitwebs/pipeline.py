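"""End-to-end orchestration: records -> three networks -> comparison report.

The pipeline loads (or simulates) a community, fits the trait regressions,
imputes the functional sizes, clusters both sides (constrained to the
species counts and unconstrained via validity-index vote), builds the
species-based and the two trait-based networks, and attaches metrics,
null-model significance and centrality to each.  Every stochastic step is
seeded from the config, so identical configs give identical reports.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np

from traitwebs import clustering, metrics, nulls
from traitwebs.build import QuantNetwork, build_species_network, build_trait_network
from traitwebs.centrality import centrality_report, most_central
from traitwebs.data import CommunityDataset, read_interactions, read_specimens, validate_community
from traitwebs.regression import (
    fit_bee_model,
    fit_plant_models,
    predict_traits,
    summarize_fits,
)
from traitwebs.simulate import paper_shaped_preset, simulate_community

__all__ = ["PipelineError", "run_pipeline", "compare_networks"]

NETWORK_MODES = ("species", "constrained", "unconstrained")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "exclude_robbing": False,
    "ie_denominator": "all_cells",
    "null_n": 1000,
    "nestedness": {"start_n": 500, "max_n": 10000, "p_tol": 0.005},
    "k_range": None,
}


class PipelineError(RuntimeError):
    """A stage failure; the message is prefixed with the stage name."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@_stage("load")
def _load(config: dict) -> tuple[CommunityDataset, dict]:
    provenance: dict[str, Any] = {}
    if "simulate" in config:
        sim = dict(config["simulate"])
        preset = sim.pop("preset", "paper")
        if preset != "paper":
            raise ValueError(f"unknown simulation preset {preset!r}")
        params = paper_shaped_preset(
            seed=sim.get("seed", config.get("seed", 0)), lam=sim.get("lam", 1.0)
        )
        ds = simulate_community(params)
        provenance["simulated"] = {"preset": preset, "seed": params.seed, "lam": params.lam}
    else:
        inp = config["input"]
        column_map = inp.get("column_map")
        records, rec_issues = read_interactions(inp["interactions"], column_map)
        specimens, spec_issues = read_specimens(inp["specimens"])
        ds = CommunityDataset(
            interactions=records,
            specimens=specimens,
            immeasurable_plant_species=set(inp.get("floor_species", [])),
        )
        provenance["inputs"] = {
            "interactions": _file_digest(inp["interactions"]),
            "specimens": _file_digest(inp["specimens"]),
        }
        provenance["load_issues"] = [
            [i.severity, i.message] for i in rec_issues + spec_issues
        ]
    if config.get("exclude_robbing"):
        ds.interactions = [r for r in ds.interactions if r.interaction_type != "robbing"]
    return ds, provenance


@_stage("traits")
def _fit_and_predict(ds: CommunityDataset) -> tuple[dict, Any]:
    bee_model = fit_bee_model(ds.specimens)
    plant_models = fit_plant_models(ds.specimens, ds.immeasurable_plant_species)
    predicted = predict_traits(ds, bee_model, plant_models)
    summary: dict[str, Any] = {
        "bee_pooled": {
            "slope": bee_model.slope,
            "intercept": bee_model.intercept,
            "r_squared": bee_model.r_squared,
            "n_points": bee_model.n_points,
        },
        "plant": {
            sp: {
                "slope": m.slope,
                "intercept": m.intercept,
                "r_squared": m.r_squared,
                "n_points": m.n_points,
            }
            for sp, m in plant_models.items()
        },
    }
    if plant_models:
        mean_r2, sd_r2, n_models = summarize_fits(list(plant_models.values()))
        summary["plant_r2_mean"] = mean_r2
        summary["plant_r2_sd"] = sd_r2
        summary["plant_n_models"] = n_models
    return summary, predicted


@_stage("cluster")
def _cluster(ds: CommunityDataset, predicted, config: dict) -> dict[str, Any]:
    ids = [r.record_id for r in ds.interactions]
    plant_species = [r.plant_species for r in ds.interactions]
    bee_species = [r.bee_species for r in ds.interactions]
    nhd = [predicted.nhd_mm[i] for i in ids]
    itd = [predicted.itd_mm[i] for i in ids]
    plant_tree = clustering.agglomerate(nhd)
    bee_tree = clustering.agglomerate(itd)
    n_plant_sp = len(set(plant_species))
    n_bee_sp = len(set(bee_species))
    out: dict[str, Any] = {
        "constrained": {
            "plant": clustering.cut_clusters(plant_tree, n_plant_sp, ids, plant_species, "plant"),
            "bee": clustering.cut_clusters(bee_tree, n_bee_sp, ids, bee_species, "bee"),
        }
    }
    k_range = config.get("k_range")
    kp, votes_p = clustering.optimal_k(nhd, k_range)
    kb, votes_b = clustering.optimal_k(itd, k_range)
    out["unconstrained"] = {
        "plant": clustering.cut_clusters(plant_tree, kp, ids, plant_species, "plant"),
        "bee": clustering.cut_clusters(bee_tree, kb, ids, bee_species, "bee"),
        "votes": {"plant": votes_p, "bee": votes_b},
    }
    return out


@_stage("build")
def _build(ds: CommunityDataset, predicted, clusters: dict) -> dict[str, QuantNetwork]:
    nets = {
        "species": build_species_network(
            ds.interactions, plant_size=predicted.nhd_mm, bee_size=predicted.itd_mm
        )
    }
    for mode in ("constrained", "unconstrained"):
        nets[mode] = build_trait_network(
            ds.interactions, clusters[mode]["plant"], clusters[mode]["bee"]
        )
    return nets


@_stage("analyse")
def _analyse(net: QuantNetwork, config: dict, seed: int) -> dict[str, Any]:
    report = metrics.metric_report(net, ie_denominator=config["ie_denominator"])
    entry: dict[str, Any] = {
        "P": net.n_plants,
        "A": net.n_bees,
        "m": net.m,
        "metrics": report.summary(),
    }
    # r2dtable z-tests for Cq, IE, H2'
    tested = {
        "Cq": metrics.weighted_connectance,
        "IE": lambda M: metrics.interaction_evenness(M, config["ie_denominator"]),
        "H2prime": metrics.h2prime,
    }
    sig: dict[str, Any] = {}
    for name, fn in tested.items():
        ens = nulls.null_distribution(net, fn, "r2dtable", n=config["null_n"], seed=seed)
        std = nulls.zscore(float(fn(np.asarray(net.matrix, dtype=float))), ens, "standard")
        sig[name] = {
            "observed": std.observed,
            "null_mean": ens.null_mean,
            "null_sd": ens.null_sd,
            "z_standard": std.z,
            "z_paper": -std.z if np.isfinite(std.z) else float("nan"),
            "p_two_sided": std.p_two_sided,
            "n": ens.n_effective,
        }
    entry["significance"] = sig
    # adaptive CRT/CCT/RCTA nestedness tests
    if net.n_plants >= 2 and net.n_bees >= 2:
        nest_cfg = config["nestedness"]
        tests = nulls.nestedness_significance(
            net,
            metrics.wnodf,
            start_n=nest_cfg["start_n"],
            max_n=nest_cfg["max_n"],
            p_tol=nest_cfg["p_tol"],
            seed=seed,
        )
        entry["nestedness"] = {
            model: {
                "observed": t.observed,
                "z_standard": t.z_standard,
                "z_paper": t.z_paper,
                "p_two_sided": t.p_two_sided,
                "n_final": t.n_final,
            }
            for model, t in tests.items()
        }
    # centrality
    cent = centrality_report(net)
    entry["centrality_top"] = {
        metric: {
            side: [
                {"node": n, "value": v, "rank": r}
                for n, v, r in most_central(cent, metric, side)[:3]
            ]
            for side in ("plant", "bee")
        }
        for metric in ("normalized_degree", "closeness", "betweenness")
    }
    return entry


def run_pipeline(config: dict) -> dict:
    """Execute the full comparison and return a JSON-serializable report."""
    cfg = {**DEFAULT_CONFIG, **config}
    cfg["nestedness"] = {**DEFAULT_CONFIG["nestedness"], **cfg.get("nestedness", {})}
    seed = int(cfg["seed"])

    ds, provenance = _load(cfg)
    validation = validate_community(ds)
    if validation.fatal:
        msgs = "; ".join(i.message for i in validation.issues if i.severity == "fatal")
        raise PipelineError(f"[validate] {msgs}")
    trait_summary, predicted = _fit_and_predict(ds)
    clusters = _cluster(ds, predicted, cfg)
    nets = _build(ds, predicted, clusters)

    report: dict[str, Any] = {
        "provenance": {"seed": seed, "config_hash": _config_hash(cfg), **provenance},
        "validation": {
            "n_records": validation.n_records,
            "n_bee_species": validation.n_bee_species,
            "n_plant_species": validation.n_plant_species,
            "issues": [[i.severity, i.message] for i in validation.issues],
        },
        "trait_models": trait_summary,
        "clustering": {
            mode: {
                "plant_k": clusters[mode]["plant"].k,
                "bee_k": clusters[mode]["bee"].k,
                **({"votes": clusters[mode]["votes"]} if "votes" in clusters[mode] else {}),
            }
            for mode in ("constrained", "unconstrained")
        },
        "networks": {},
    }
    for i, mode in enumerate(NETWORK_MODES):
        report["networks"][mode] = _analyse(nets[mode], cfg, seed + 104729 * i)
    return report


def compare_networks(report: dict) -> list[dict]:
    """Side-by-side parameter table with deltas against the species network.

    One row per network-level parameter plus the node-level means +- SD;
    deltas are (mode - species).
    """
    rows: list[dict] = []
    modes = [m for m in NETWORK_MODES if m in report["networks"]]
    base = report["networks"]["species"]["metrics"]
    params = [
        "Cq",
        "WNODF",
        "IE",
        "H2prime",
        "d_prime_bee_mean",
        "d_prime_plant_mean",
        "strength_bee_mean",
        "strength_plant_mean",
    ]
    for param in params:
        row: dict[str, Any] = {"parameter": param}
        for mode in modes:
            entry = report["networks"][mode]
            value = entry["metrics"][param]
            row[mode] = value
            if mode != "species":
                row[f"delta_{mode}"] = value - base[param]
            sd_key = param.replace("_mean", "_sd")
            if param.endswith("_mean") and sd_key in entry["metrics"]:
                row[f"{mode}_sd"] = entry["metrics"][sd_key]
            sig = entry.get("significance", {}).get(param)
            if sig:
                row[f"{mode}_z_paper"] = sig["z_paper"]
                row[f"{mode}_p"] = sig["p_two_sided"]
        rows.append(row)
    return rows
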