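"""End-to-end orchestration: correlations -> causality -> sensitivity.

A :class:`RunConfig` (plain key=value text file) points at a trait table
and tree file (or a synthetic preset), picks the scale (test or full) and
seeds, and the stage runners produce tidy TSV/JSON outputs plus a
markdown report.  Every threshold, seed and prior actually used is
recorded in a JSON-lines log.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestral import (HiddenRateModel, ancestral_value_regression,
                        classify_nodes, count_origins, select_hrm)
from .bpmm import PhyloMixedModel
from .coevolution import DiscretePairCoevolution, bayes_factor
from .pathmodel import run_candidate_set
from .traits import build_analysis_table, binarize_traits, load_species_table
from .treeio import Phylogeny, read_trees

__all__ = ["RunConfig", "SCALES", "load_inputs", "run_correlations",
           "run_causality", "run_sensitivity", "run_all"]

SCALES = {
    "test": {
        "bpmm_iterations": 4_000, "bpmm_burn_in": 500, "bpmm_thinning": 5,
        "ss_stones": 12, "ss_iters": 120, "ss_burn": 40,
        "rj_iterations": 4_000, "rj_burn_in": 500, "rj_thinning": 2,
        "hrm_classes": (1, 2), "hrm_structures": ("er", "ard"),
    },
    # the full-scale settings; never exercised by the test suite
    "paper": {
        "bpmm_iterations": 1_100_000, "bpmm_burn_in": 100_000, "bpmm_thinning": 1_000,
        "ss_stones": 32, "ss_iters": 1_000, "ss_burn": 300,
        "rj_iterations": 11_000_000, "rj_burn_in": 1_000_000, "rj_thinning": 5_000,
        "hrm_classes": (1, 2, 3), "hrm_structures": ("er", "sym", "ard"),
    },
}


@dataclass
class RunConfig:
    trait_table: str | None = None
    trees: str | None = None
    out_dir: str = "antpath_out"
    scale: str = "test"
    seed: int = 1
    preset: str | None = None          # synthetic preset instead of files
    n_species: int = 200
    colony_rule: str = "median"
    mating_threshold: float = 2.0
    stages: tuple = ("correlations", "causality", "sensitivity")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Parse a ``key = value`` per-line config file."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in fields:
                    raise KeyError(f"unknown config key {key!r}")
                typ = fields[key].type
                if key == "stages":
                    kwargs[key] = tuple(s.strip() for s in val.split(","))
                elif typ in ("int", int):
                    kwargs[key] = int(val)
                elif typ in ("float", float):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val
        cfg = cls(**kwargs)
        for f in ("trait_table", "trees"):
            p = getattr(cfg, f)
            if p and not os.path.exists(p):
                raise FileNotFoundError(f"{f}: {p}")
        return cfg


class _Log:
    def __init__(self, path):
        self.path = path
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        self._fh = open(path, "a")

    def write(self, **record):
        self._fh.write(json.dumps(record, default=str) + "\n")
        self._fh.flush()


def load_inputs(config: RunConfig):
    """Analysis table + tree from files or from the synthetic generator."""
    if config.preset:
        from .simulate import generate_species_table

        ds = generate_species_table(config.preset, config.n_species, seed=config.seed)
        table = ds.analysis_table
        tree = ds.tree
    else:
        if not (config.trait_table and config.trees):
            raise ValueError("config needs trait_table and trees, or a preset")
        records = load_species_table(config.trait_table)
        table, _ = build_analysis_table(
            records, colony_rule=config.colony_rule,
            mating_threshold=config.mating_threshold,
        )
        sample = read_trees(config.trees)
        tree = sample[0]
    return table, tree


_PAIRWISE = [
    # (response, predictor, family) — the six pairwise trait models
    ("castes", "log10_colony_size", "poisson_log"),
    ("castes", "log10_mating_frequency", "poisson_log"),
    ("castes", "log10_queen_number", "poisson_log"),
    ("log10_mating_frequency", "log10_queen_number", "gaussian"),
    ("log10_colony_size", "log10_mating_frequency", "gaussian"),
    ("log10_colony_size", "log10_queen_number", "gaussian"),
]
_CV_MODELS = [
    ("sqrt_worker_cv", "log10_colony_size", "gaussian"),
    ("sqrt_worker_cv", "log10_mating_frequency", "gaussian"),
    ("sqrt_worker_cv", "log10_queen_number", "gaussian"),
]


def run_correlations(table: pd.DataFrame, tree: Phylogeny, scale: str = "test",
                     seed: int = 1, log: _Log | None = None) -> pd.DataFrame:
    """The pairwise BPMMs plus the worker-size-variation models."""
    s = SCALES[scale]
    rows = []
    for resp, pred, family in _PAIRWISE + _CV_MODELS:
        if resp not in table.columns or pred not in table.columns:
            rows.append({"response": resp, "predictor": pred,
                         "error": "missing column"})
            continue
        try:
            model = PhyloMixedModel.from_dataframe(
                f"{resp} ~ {pred}", table, tree, family=family)
            res = model.fit(iterations=s["bpmm_iterations"],
                            burn_in=s["bpmm_burn_in"],
                            thinning=s["bpmm_thinning"], seed=seed)
            summ = res.summary().set_index("parameter")
            slope = summ.loc[pred]
            row = {
                "response": resp, "predictor": pred, "family": family,
                "n_species": len(model.y),
                "beta_mode": slope["post_mode"],
                "ci_lower": slope["ci_lower"], "ci_upper": slope["ci_upper"],
                "significant": bool(slope["significant"]),
            }
            if family == "gaussian":
                row["marginal_r2_median"] = res.marginal_r2()["median"]
            rows.append(row)
            if log:
                log.write(stage="correlations", response=resp, predictor=pred,
                          family=family, seed=seed, **{k: s[k] for k in
                          ("bpmm_iterations", "bpmm_burn_in", "bpmm_thinning")})
        except Exception as exc:
            rows.append({"response": resp, "predictor": pred, "error": str(exc)})
    return pd.DataFrame(rows)


def run_causality(table: pd.DataFrame, tree: Phylogeny, scale: str = "test",
                  seed: int = 1, log: _Log | None = None) -> dict:
    """Path analysis, transition rates and ancestral reconstruction.

    Returns a consolidated report stating, per method, whether the
    colony-size -> worker-castes direction is supported, plus an agreement
    summary.  Per-stage failures are isolated into the report.
    """
    s = SCALES[scale]
    report: dict = {"methods": {}}

    # (1) phylogenetic path analysis
    try:
        path = run_candidate_set(table, tree, response_mode="castes_binary")
        top = path["ranking"].iloc[0]
        supports = top["model"] in ("model_1", "model_3")
        report["methods"]["path_analysis"] = {
            "top_model": top["model"], "omega_top": float(top["omega"]),
            "supports_size_to_castes": bool(supports),
            "n_species": path["n"],
            "ranking": path["ranking"].to_dict(orient="records"),
        }
    except Exception as exc:
        report["methods"]["path_analysis"] = {"error": str(exc)}

    # (2) transition-rate analysis on (colony class, caste binary)
    try:
        work = table.dropna(subset=["colony_size", "castes"])
        work = binarize_traits(work)
        states = {
            r["species"]: (1 if r["colony_size_class"] == "large" else 0,
                           1 if r["castes"] > 1 else 0)
            for _, r in work.iterrows()
        }
        ptree = tree.prune_to_taxa(list(states)).scale_branches(1.0)
        model = DiscretePairCoevolution(ptree, states)
        ml_dep = model.stepping_stone("dependent", n_stones=s["ss_stones"],
                                      iters_per_stone=s["ss_iters"],
                                      burn_per_stone=s["ss_burn"], seed=seed)
        ml_ind = model.stepping_stone("independent", n_stones=s["ss_stones"],
                                      iters_per_stone=s["ss_iters"],
                                      burn_per_stone=s["ss_burn"], seed=seed + 1)
        bf = bayes_factor(ml_dep.log_ml, ml_ind.log_ml)
        chain = model.rjmcmc("dependent", iterations=s["rj_iterations"],
                             burn_in=s["rj_burn_in"], thinning=s["rj_thinning"],
                             seed=seed)
        zp = chain.zero_rate_proportion("gain2|1=0")
        report["methods"]["transition_rates"] = {
            "bayes_factor": bf.bf, "evidence": bf.label,
            "log_ml_dependent": ml_dep.log_ml, "log_ml_independent": ml_ind.log_ml,
            "zero_proportion_gain_in_small": zp,
            "supports_size_to_castes": bool(bf.bf > 2 and zp > 0.5),
            "n_species": len(states),
            "rate_summary": chain.summary().to_dict(orient="records"),
        }
    except Exception as exc:
        report["methods"]["transition_rates"] = {"error": str(exc)}

    # (3) ancestral state reconstruction + ancestral-value contrast
    try:
        work = table.dropna(subset=["castes"])
        tips = {r["species"]: (1 if r["castes"] > 1 else 0)
                for _, r in work.iterrows()}
        ptree = tree.prune_to_taxa(list(tips))
        sel = select_hrm([ptree], tips, n_obs=2,
                         candidates=[(c, st) for c in s["hrm_classes"]
                                     for st in s["hrm_structures"]],
                         seed=seed)
        win = sel["winner"]
        fit = HiddenRateModel(ptree, tips, n_obs=2,
                              n_rate_classes=win["n_rate_classes"],
                              structure=win["structure"]).fit(seed=seed)
        assigned = fit.marginal_states().assigned_states()
        cats = classify_nodes(ptree, assigned)
        origins = count_origins(ptree, assigned)
        sizes = {r["species"]: r["log10_colony_size"]
                 for _, r in table.iterrows()
                 if np.isfinite(r.get("log10_colony_size", np.nan))}
        est = ancestral_value_regression(
            ptree, cats, sizes, iterations=s["bpmm_iterations"],
            burn_in=s["bpmm_burn_in"], thinning=s["bpmm_thinning"], seed=seed)
        c1 = est.categories[1]
        c2 = est.categories[2]
        supports = (est.pmcmc_1_vs_2 is not None and est.pmcmc_1_vs_2 < 0.05
                    and c2["mode"] > c1["mode"])
        report["methods"]["ancestral_reconstruction"] = {
            "hrm_winner": win, "win_fraction": sel["win_fraction"],
            "n_origins": origins,
            "ancestral_log10_size_single": c1, "ancestral_log10_size_pre_multiple": c2,
            "pmcmc_1_vs_2": est.pmcmc_1_vs_2,
            "supports_size_to_castes": bool(supports),
        }
    except Exception as exc:
        report["methods"]["ancestral_reconstruction"] = {"error": str(exc)}

    votes = {k: v.get("supports_size_to_castes")
             for k, v in report["methods"].items() if "error" not in v}
    report["agreement"] = votes
    report["n_methods_supporting"] = sum(bool(v) for v in votes.values())
    if log:
        log.write(stage="causality", seed=seed, agreement=votes)
    return report


def run_sensitivity(table: pd.DataFrame, tree: Phylogeny, scale: str = "test",
                    seed: int = 1, log: _Log | None = None) -> pd.DataFrame:
    """Robustness variants: categorical recodings and quantile thresholds."""
    s = SCALES[scale]
    rows = []

    # categorical recodings of mating frequency / queen number
    for cat_col, scheme in [("mating_category", "three_level"),
                            ("queen_category", "three_level"),
                            ("obligate_polyandry_binary", "obligate_binary"),
                            ("obligate_polygyny_binary", "obligate_binary")]:
        variant = f"castes ~ {cat_col} ({scheme})"
        if cat_col not in table.columns or table[cat_col].dropna().nunique() < 2:
            rows.append({"variant": variant, "skipped": True,
                         "note": "fewer than two levels present"})
            continue
        try:
            model = PhyloMixedModel.from_dataframe(
                f"castes ~ 0 + {cat_col}", table, tree, family="poisson_log")
            res = model.fit(iterations=s["bpmm_iterations"],
                            burn_in=s["bpmm_burn_in"],
                            thinning=s["bpmm_thinning"], seed=seed)
            levels = model.exog_names
            p = res.pmcmc(levels[0], levels[-1]) if len(levels) >= 2 else None
            rows.append({"variant": variant, "skipped": False,
                         "n_levels": len(levels), "pmcmc_extremes": p,
                         "n_species": len(model.y)})
        except Exception as exc:
            rows.append({"variant": variant, "skipped": True, "note": str(exc)})

    # colony-size threshold variants for the transition-rate stage
    for rule in ("q40", "median", "q60"):
        variant = f"transition rates, colony rule {rule}"
        try:
            work = table.dropna(subset=["colony_size", "castes"])
            work = binarize_traits(work, colony_rule=rule)
            thr = work.attrs["colony_size_threshold"]
            states = {
                r["species"]: (1 if r["colony_size_class"] == "large" else 0,
                               1 if r["castes"] > 1 else 0)
                for _, r in work.iterrows()
            }
            ptree = tree.prune_to_taxa(list(states))
            model = DiscretePairCoevolution(ptree, states)
            dep = model.fit_ml("dependent", seed=seed)
            ind = model.fit_ml("independent", seed=seed)
            lrt = 2 * (dep.loglik - ind.loglik)
            rows.append({"variant": variant, "skipped": False,
                         "threshold": thr, "lnL_dep": dep.loglik,
                         "lnL_ind": ind.loglik, "lr_statistic": lrt,
                         "gain_in_small_rate": float(dep.rates[4])})
            if log:
                log.write(stage="sensitivity", variant=variant, threshold=thr,
                          seed=seed)
        except Exception as exc:
            rows.append({"variant": variant, "skipped": True, "note": str(exc)})
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Run every configured stage, writing outputs under ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    log = _Log(os.path.join(config.out_dir, "run_log.jsonl"))
    log.write(stage="start", config=dataclasses.asdict(config))
    table, tree = load_inputs(config)
    out = {}
    if "correlations" in config.stages:
        corr = run_correlations(table, tree, config.scale, config.seed, log)
        corr.to_csv(os.path.join(config.out_dir, "correlations.tsv"),
                    sep="\t", index=False)
        out["correlations"] = corr
    if "causality" in config.stages:
        causal = run_causality(table, tree, config.scale, config.seed, log)
        with open(os.path.join(config.out_dir, "causality.json"), "w") as fh:
            json.dump(causal, fh, indent=1, default=float)
        out["causality"] = causal
    if "sensitivity" in config.stages:
        sens = run_sensitivity(table, tree, config.scale, config.seed, log)
        sens.to_csv(os.path.join(config.out_dir, "sensitivity.tsv"),
                    sep="\t", index=False)
        out["sensitivity"] = sens
    _write_report(config, out)
    return out


def _write_report(config: RunConfig, out: dict) -> None:
    lines = ["# antpath run report", "",
             f"- scale: {config.scale}", f"- seed: {config.seed}", ""]
    if "correlations" in out:
        lines += ["## Trait correlations (BPMMs)", "",
                  out["correlations"].to_string(index=False), ""]
    if "causality" in out:
        causal = out["causality"]
        lines += ["## Causality analyses", ""]
        for method, res in causal["methods"].items():
            if "error" in res:
                lines.append(f"- {method}: FAILED ({res['error']})")
            else:
                lines.append(
                    f"- {method}: supports size->castes = "
                    f"{res['supports_size_to_castes']}")
        lines += ["", f"Methods supporting the size-complexity direction: "
                      f"{causal['n_methods_supporting']}", ""]
    if "sensitivity" in out:
        lines += ["## Sensitivity variants", "",
                  out["sensitivity"].to_string(index=False), ""]
    with open(os.path.join(config.out_dir, "report.md"), "w") as fh:
        fh.write("\n".join(lines))
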