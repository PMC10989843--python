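"""End-to-end workflow: simulate/load -> beta-diversity -> networks ->
topology/roles/eigengenes -> robustness -> NST, from a single config.

The run directory receives input tables, one GraphML + edge list per
network scope, JSON topology summaries, robustness and NST tables, a
``summary.json`` aggregating the headline numbers, a manifest recording
seeds and the config hash, and a log file.  Reruns with an identical
config are deterministic (byte-identical summary) and skip completed
stages via the recorded config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta as beta_mod
from . import io as io_mod
from .core import OtuTable, community_distance, rarefy
from .network import prevalence_filter, similarity_matrix, threshold_network
from .nst import nst, nst_compare
from .robustness import robustness_compare, robustness_random, robustness_targeted
from .roles import module_eigengene, eigengene_env_correlation, zi_pi
from .simulate import CommunityParams, EnvParams, generate_counts, generate_design, generate_env
from .topology import greedy_modules, powerlaw_fit, random_null_ensemble, relative_modularity, topology_summary

logger = logging.getLogger("seasonet")

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "inputs": None,  # {"otu": path, "meta": path, "env": path} to load real data
    "simulate": {
        "n_blocks": 4,
        "n_months": 12,
        "n_otus": 600,
        "n_modules": 5,
        "module_size": 20,
        "assoc_strength": 0.95,
        "depth": 17700,
    },
    "rarefaction_depth": 17700,
    "beta": {
        "metric": "bray_curtis",
        "dispersion_metric": "sorensen",
        "n_perm": 999,
        "terms": ["treatment", "month", "treatment:month", "block"],
    },
    "network": {
        "prevalence_fraction": 0.75,
        "transform": "log10_pseudocount",
        "seasonal_s_t": 0.890,
        "global_s_t": 0.680,
    },
    "topology": {"n_nulls": 30},
    "robustness": {"fraction": 0.5, "n_hubs": 5, "n_reps": 100},
    "nst": {"grouping": "treatment_season", "metric": "jaccard", "n_rand": 200,
            "n_perm": 1000},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


class PipelineConfig:
    """Validated pipeline configuration (defaults merged in)."""

    def __init__(self, raw: dict | None = None):
        self.raw = _merge(DEFAULT_CONFIG, raw)
        if self.raw["inputs"] is None and self.raw["simulate"] is None:
            raise ValueError("config needs either 'inputs' paths or a 'simulate' block")
        sim = self.raw["simulate"]
        if sim is not None:
            n_scope = 2 * sim["n_blocks"]  # smallest scope: one season x treatment
            months_per_season = min(3, sim["n_months"])
            if n_scope * months_per_season < 4:
                raise ValueError(
                    "smallest network scope selects fewer than 4 samples"
                )
        self.seed = int(self.raw["seed"])

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()

    def stage_seed(self, counter: int) -> int:
        # counter-based fan-out; recorded in the manifest
        return (self.seed * 1_000_003 + counter) % (2**31 - 1)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig(yaml.safe_load(fh) or {})


def _round(x, nd=8):
    if isinstance(x, (float, np.floating)):
        x = float(x)
        return None if np.isnan(x) else round(x, nd)  # NaN -> JSON null
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def _network_scopes(meta: pd.DataFrame, netcfg: dict) -> list[dict]:
    """Two global + eight seasonal scopes, as in the study design."""
    scopes = []
    for trt in ("warming", "control"):
        scopes.append({
            "name": f"global_{trt}",
            "samples": list(meta.index[meta["treatment"] == trt]),
            "s_t": netcfg["global_s_t"],
        })
    for season in ("spring", "summer", "fall", "winter"):
        for trt in ("warming", "control"):
            sel = meta.index[(meta["treatment"] == trt) & (meta["season"] == season)]
            if len(sel):
                scopes.append({
                    "name": f"{season}_{trt}",
                    "samples": list(sel),
                    "s_t": netcfg["seasonal_s_t"],
                })
    for sc in scopes:
        if len(sc["samples"]) < 4:
            raise ValueError(f"scope {sc['name']} selects fewer than 4 samples")
    return scopes


def run_pipeline(config: PipelineConfig | dict, out_dir) -> dict:
    """Run the full workflow; returns the summary dict (also written as
    ``summary.json`` in the run directory)."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "networks").mkdir(exist_ok=True)

    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    digest = config.digest()
    manifest_path = out / "manifest.json"
    summary_path = out / "summary.json"
    if manifest_path.exists() and summary_path.exists():
        try:
            prev = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            prev = {}
        if prev.get("config_sha256") == digest:
            logger.info("config unchanged; reusing completed run")
            logger.removeHandler(handler)
            return json.loads(summary_path.read_text())

    seeds = {name: config.stage_seed(i) for i, name in enumerate(
        ["simulate", "beta", "topology", "robustness", "nst"]
    )}
    summary: dict = {}

    try:
        # ---------------- stage 1: inputs -------------------------------
        if config.raw["inputs"] is not None:
            paths = config.raw["inputs"]
            table = io_mod.read_otu_table(paths["otu"])
            meta = io_mod.read_metadata(paths["meta"])
            env = io_mod.read_env_table(paths["env"], table.sample_ids)
            truth = None
        else:
            sim = config.raw["simulate"]
            meta = generate_design(sim["n_blocks"], sim["n_months"])
            env = generate_env(meta, EnvParams(), seed=seeds["simulate"])
            cp = CommunityParams(
                n_otus=sim["n_otus"], n_modules=sim["n_modules"],
                module_size=sim["module_size"],
                assoc_strength=sim["assoc_strength"], depth=sim["depth"],
            )
            table, truth = generate_counts(meta, env, cp, seed=seeds["simulate"] + 1)
            (out / "truth.json").write_text(truth.to_json())
        depth = config.raw["rarefaction_depth"]
        if depth and (table.depths > depth).any():
            table = rarefy(table, depth, seed=seeds["simulate"] + 2)
        meta = meta.loc[table.sample_ids]
        io_mod.write_otu_table(table, out / "otu.tsv")
        io_mod.write_metadata(meta, out / "meta.tsv")
        io_mod.write_env_table(env, out / "env.tsv")
        summary["design"] = {
            "n_samples": len(table.sample_ids),
            "n_otus": len(table.otu_ids),
            "depth": int(table.depths.iloc[0]),
        }

        # ---------------- stage 2: beta diversity -----------------------
        bcfg = config.raw["beta"]
        dist = community_distance(table, bcfg["metric"])
        ord_res = beta_mod.pcoa(dist)
        ord_res.to_dataframe().to_csv(out / "pcoa.tsv", sep="\t")
        perm = beta_mod.permanova(
            dist, meta, terms=tuple(bcfg["terms"]),
            n_perm=bcfg["n_perm"], seed=seeds["beta"],
        )
        pd.DataFrame(
            [{"term": r.statistic_name, "F": r.observed, "df": r.df,
              "R2": r.r_squared, "p": r.p_value} for r in perm]
        ).to_csv(out / "permanova.tsv", sep="\t", index=False)
        disp_dist = community_distance(table, bcfg["dispersion_metric"])
        disp, dist_to_centroid = beta_mod.beta_dispersion(
            disp_dist, meta["treatment"], n_perm=bcfg["n_perm"],
            seed=seeds["beta"] + 1,
        )
        dist_to_centroid.to_frame().to_csv(out / "dispersion_distances.tsv", sep="\t")
        pairs, fit = beta_mod.paired_divergence_curve(dist, meta)
        pairs.to_csv(out / "divergence_pairs.tsv", sep="\t", index=False)
        env_z = (env - env.mean()) / env.std(ddof=0)
        env_d = np.sqrt(
            ((env_z.values[:, None, :] - env_z.values[None, :, :]) ** 2).sum(-1)
        )
        env_d = env_d / env_d.max() if env_d.max() > 0 else env_d
        mantel_res = beta_mod.mantel(
            dist,
            beta_mod.CommunityDistance(list(env.index), env_d, "euclidean_env"),
            n_perm=bcfg["n_perm"], seed=seeds["beta"] + 2,
        )
        summary["beta"] = {
            "permanova": {
                r.statistic_name: {"F": r.observed, "df": r.df,
                                   "R2": r.r_squared, "p": r.p_value}
                for r in perm
            },
            "dispersion_treatment": {"F": disp.observed, "p": disp.p_value},
            "divergence_fit": fit,
            "mantel_env": {"r": mantel_res.observed, "p": mantel_res.p_value},
        }

        # ---------------- stage 3-4: networks + topology ----------------
        netcfg = config.raw["network"]
        topocfg = config.raw["topology"]
        robcfg = config.raw["robustness"]
        scopes = _network_scopes(meta, netcfg)
        summary["networks"] = {}
        robustness_results = {}
        for i, scope in enumerate(scopes):
            filtered = prevalence_filter(
                table, scope["samples"], netcfg["prevalence_fraction"]
            )
            sim_mat = similarity_matrix(filtered, netcfg["transform"])
            net = threshold_network(
                sim_mat, scope["s_t"], table=filtered,
                sample_ids=scope["samples"],
                prevalence_fraction=netcfg["prevalence_fraction"],
                transform=netcfg["transform"],
            )
            entry: dict = {"s_t": scope["s_t"], "n": net.n_nodes, "L": net.n_links}
            if net.n_links == 0:
                summary["networks"][scope["name"]] = entry
                continue
            modules = greedy_modules(net)
            roles = zi_pi(net, modules)
            topo = topology_summary(net)
            exponent, r2 = powerlaw_fit([d for _, d in net.graph.degree()])
            nulls = random_null_ensemble(
                net, n_reps=topocfg["n_nulls"], seed=seeds["topology"] + i
            )
            rm = (
                relative_modularity(modules.modularity, nulls["modularity"]["mean"])
                if nulls["modularity"]["mean"] > 0 else None
            )
            for role in roles:
                net.graph.nodes[role.otu_id].update(
                    module=role.module_id, Zi=role.zi, Pi=role.pi,
                    role=role.category,
                )
            io_mod.write_network(net, out / "networks" / f"{scope['name']}.graphml")
            io_mod.write_network(
                net, out / "networks" / f"{scope['name']}_edges.tsv",
                format="edge_list_tsv",
            )
            pd.DataFrame([dataclasses.asdict(r) for r in roles]).to_csv(
                out / "networks" / f"{scope['name']}_roles.tsv", sep="\t", index=False
            )
            sub = filtered.subset_otus([n for n in net.graph.nodes])
            eigs = module_eigengene(sub, modules)
            if eigs:
                pd.DataFrame({e.module_id: e.scores for e in eigs}).to_csv(
                    out / "networks" / f"{scope['name']}_eigengenes.tsv", sep="\t"
                )
                env_corr = eigengene_env_correlation(eigs, env.loc[scope["samples"]])
                env_corr.to_csv(
                    out / "networks" / f"{scope['name']}_module_env.tsv",
                    sep="\t", index=False,
                )
            abund = (
                filtered.counts[scope["samples"]]
                .div(filtered.counts[scope["samples"]].sum(axis=0), axis=1)
                .mean(axis=1)
            )
            abund = abund.loc[[n for n in net.graph.nodes]]
            rnd = robustness_random(
                net, abund, fraction=robcfg["fraction"],
                n_reps=robcfg["n_reps"], seed=seeds["robustness"] + 2 * i,
            )
            tgt = robustness_targeted(
                net, abund, roles, n_hubs=robcfg["n_hubs"],
                n_reps=robcfg["n_reps"], seed=seeds["robustness"] + 2 * i + 1,
            )
            robustness_results[scope["name"]] = {"random": rnd, "targeted": tgt}
            entry.update({
                "avgK": topo.avgK, "avgCC": topo.avgCC,
                "connectance": topo.connectance, "GD": topo.GD,
                "unreachable_pairs": topo.unreachable_pairs,
                "powerlaw_exponent": exponent, "powerlaw_r2": r2,
                "modularity": modules.modularity,
                "is_modular": modules.is_modular,
                "n_modules": len(modules.modules),
                "relative_modularity": rm,
                "positive_link_fraction": net.positive_link_fraction,
                "n_module_hubs": sum(
                    r.category in ("module_hub", "network_hub") for r in roles
                ),
                "n_connectors": sum(r.category == "connector" for r in roles),
                "null": {k: {kk: vv for kk, vv in v.items() if kk != "values"}
                         for k, v in nulls.items() if isinstance(v, dict)},
                "robustness_random": {"mean": rnd.mean, "sd": rnd.sd},
                "robustness_targeted": {"mean": tgt.mean, "sd": tgt.sd},
            })
            summary["networks"][scope["name"]] = entry
        # warming vs control comparison on the global networks
        if {"global_warming", "global_control"} <= set(robustness_results):
            comp = {}
            for mode in ("random", "targeted"):
                t, df, p = robustness_compare(
                    robustness_results["global_warming"][mode],
                    robustness_results["global_control"][mode],
                )
                comp[mode] = {"t": t, "df": df, "p": p}
            summary["robustness_warming_vs_control"] = comp

        # ---------------- stage 5: NST ----------------------------------
        ncfg = config.raw["nst"]
        nst_res = nst(
            table, meta, grouping=ncfg["grouping"], metric=ncfg["metric"],
            n_rand=ncfg["n_rand"], seed=seeds["nst"],
        )
        pd.DataFrame(
            [{"group": g, "NST_percent": r.nst_percent, "n_pairs": len(r.pairs)}
             for g, r in nst_res.items()]
        ).to_csv(out / "nst.tsv", sep="\t", index=False)
        summary["nst_percent"] = {g: r.nst_percent for g, r in nst_res.items()}
        if ncfg["grouping"] == "treatment_season":
            comps = {}
            for season in ("spring", "summer", "fall", "winter"):
                ga, gb = f"warming:{season}", f"control:{season}"
                if ga in nst_res and gb in nst_res:
                    union = nst_res[ga].sample_ids + nst_res[gb].sample_ids
                    pooled = _nst_pooled(
                        table, union, season, ncfg, seed=seeds["nst"] + 17
                    )
                    comps[season] = nst_compare(
                        nst_res[ga], nst_res[gb], pooled=pooled,
                        n_perm=ncfg["n_perm"], seed=seeds["nst"] + 31,
                    )
            summary["nst_warming_vs_control"] = comps

        summary = _round(summary)
        summary_path.write_text(json.dumps(summary, sort_keys=True, indent=1))
        manifest = {
            "config_sha256": digest,
            "config": config.raw,
            "seeds": seeds,
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))
        return summary
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _nst_pooled(table, union, season, ncfg, seed):
    from .nst import _nst_one_group

    return _nst_one_group(
        table, union, f"pooled:{season}", ncfg["metric"],
        "proportional_occurrence_fixed_richness", ncfg["n_rand"], seed,
    )
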