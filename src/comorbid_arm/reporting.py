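"""Pipeline orchestration, rule-network export and run provenance.

The rule network uses the bipartite rule-vertex convention familiar from
arulesViz-style graphs: item nodes carry their support; each rule becomes
an intermediate vertex carrying support, confidence, lift and IS, with
edges antecedent-items -> rule-vertex -> consequent item.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import yaml

from . import __version__
from .arm import mine_rules, rules_frame
from .mortality import (
    fit_mortality_models,
    forest_plot_data,
    odds_ratio_report,
    render_forest_plot,
)
from .phenotyping import CodeMap, default_code_map, phenotype_cohort
from .records import filter_cohort, read_cohort, write_cohort
from .simulate import SyntheticCohortConfig, generate_cohort
from .stats import prevalence_frame

logger = logging.getLogger(__name__)

__all__ = ["build_rule_graph", "export_rule_graph", "run_pipeline"]


def build_rule_graph(rules, item_supports: dict | None = None) -> nx.DiGraph:
    """Bipartite item/rule-vertex digraph from ranked rules.

    Node attribute ``support`` sizes the vertices; rule vertices also
    carry confidence, lift and IS (the published layout colors by lift).
    """
    g = nx.DiGraph()
    if not rules:
        logger.warning("no rules to export: emitting an empty graph")
        return g
    item_supports = item_supports or {}
    for i, rule in enumerate(rules, start=1):
        rid = f"rule_{i}"
        g.add_node(
            rid,
            kind="rule",
            label=rule.label,
            support=float(rule.support),
            confidence=float(rule.confidence),
            lift=float(rule.lift),
            IS=float(rule.is_score),
        )
        for item in sorted(rule.antecedent) + sorted(rule.consequent):
            if item not in g:
                g.add_node(
                    item, kind="item",
                    support=float(item_supports.get(item, float("nan"))),
                )
        for item in sorted(rule.antecedent):
            g.add_edge(item, rid)
        for item in sorted(rule.consequent):
            g.add_edge(rid, item)
    return g


def _write_dot(g: nx.DiGraph, path) -> None:
    # minimal hand-rolled DOT writer (no pydot/pygraphviz dependency)
    def quote(s):
        return '"' + str(s).replace('"', r"\"") + '"'

    lines = ["digraph rules {"]
    for node, data in g.nodes(data=True):
        attrs = ", ".join(
            f"{k}={quote(v)}" for k, v in sorted(data.items())
        )
        lines.append(f"  {quote(node)} [{attrs}];")
    for u, v in g.edges():
        lines.append(f"  {quote(u)} -> {quote(v)};")
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def export_rule_graph(rules, graphml_path, dot_path=None, item_supports=None):
    """Write the rule network as GraphML (and optionally DOT)."""
    g = build_rule_graph(rules, item_supports)
    nx.write_graphml(g, graphml_path)
    if dot_path is not None:
        _write_dot(g, dot_path)
    return g


DEFAULT_CONFIG = {
    "simulate": {"n": 170_000, "seed": 0},
    "input_csv": None,
    "code_map": None,  # path to a YAML code map; None = package default
    "thresholds": {
        "min_support": 0.01,
        "min_confidence": 0.1,
        "min_lift": 1.0,
        "max_consequent_size": 1,
    },
    "include_other_site": True,
    "family_size": None,  # Bonferroni m; None = number of tests in the table
    "mortality_subsets": [
        "All cancer", "Stomach cancer", "Colorectal cancer",
        "Liver cancer", "Lung cancer",
    ],
    "include_surgery_control": True,
}


def _merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (user or {}).items():
        if key not in cfg:
            raise KeyError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: dict | None = None, out_dir="results") -> Path:
    """simulate/load -> filter -> phenotype -> prevalence -> rules ->
    mortality -> graph -> manifest.

    Returns the output directory; every stage output is a pure function
    of (input file, config, seed), so the manifest hash is rerun-stable.
    """
    cfg = _merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg["input_csv"]:
        cohort = read_cohort(cfg["input_csv"])
        seed = None
    else:
        sim = SyntheticCohortConfig.from_dict(cfg["simulate"])
        seed = sim.seed
        cohort = generate_cohort(sim)
        write_cohort(cohort, out / "cohort.csv")
    n_raw = cohort.n

    cohort = filter_cohort(cohort)
    code_map = (
        CodeMap.from_yaml(cfg["code_map"]) if cfg["code_map"] else default_code_map()
    )
    profiles = phenotype_cohort(cohort, code_map)

    # prevalence tables
    for stratifier, fname in [
        ("sex", "prevalence_by_sex.tsv"),
        ("age_group", "prevalence_by_age.tsv"),
        ("cancer_site", "prevalence_by_site.tsv"),
    ]:
        frames = []
        for condition in ("dm", "htn"):
            f = prevalence_frame(profiles, stratifier, condition)
            f = f.rename(
                columns={f"n_{condition}": f"n_{condition}", "pct": f"pct_{condition}"}
            )
            frames.append(f.set_index([stratifier, "n_total"]))
        table = frames[0].join(frames[1:]).reset_index()
        table.to_csv(out / fname, sep="\t", index=False)

    # association rules
    th = cfg["thresholds"]
    rules = mine_rules(
        profiles,
        min_support=th["min_support"],
        min_confidence=th["min_confidence"],
        min_lift=th["min_lift"],
        max_consequent_size=th["max_consequent_size"],
        include_other=cfg["include_other_site"],
    )
    rules_frame(rules).to_csv(out / "rules.tsv", sep="\t", index=False)

    from .arm import build_transactions

    transactions, n_tx = build_transactions(
        profiles, include_other=cfg["include_other_site"]
    )
    item_supports = {}
    for t in transactions:
        for item in t:
            item_supports[item] = item_supports.get(item, 0) + 1
    item_supports = {k: v / n_tx for k, v in item_supports.items()}
    export_rule_graph(
        rules, out / "rules.graphml", out / "rules.dot", item_supports
    )

    # mortality models
    fits = fit_mortality_models(
        profiles,
        subsets=cfg["mortality_subsets"],
        include_surgery=cfg["include_surgery_control"],
    )
    for label, fit in fits.items():
        fname = "mortality_" + label.lower().replace(" ", "_") + ".tsv"
        odds_ratio_report(fit).to_csv(out / fname, sep="\t", index=False)
    plot_df = forest_plot_data(fits)
    plot_df.to_csv(out / "forest_data.tsv", sep="\t", index=False)
    render_forest_plot(plot_df, out / "forest_plot.svg")

    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "n_input_records": n_raw,
        "n_after_filter": cohort.n,
        "n_profiles": int(len(profiles)),
        "n_rules": len(rules),
        "mortality_models": {
            label: {
                "n_used": fit.n_used,
                "converged": fit.converged,
                "dropped_terms": fit.dropped_terms,
            }
            for label, fit in fits.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %d records, %d rules -> %s", n_raw, len(rules), out)
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
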