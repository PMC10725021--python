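"""End-to-end study orchestration.

Reproduces the full multi-network study design on any cohort, real or
synthetic: descriptives; the insomnia-only network; one network per factor
domain (insomnia items + that domain); domain screening (a domain enters
the integrated models only if at least one of its nodes shares an edge with
a symptom); integrated total-score and item-level networks; covariate-
adjusted variants (depression severity and medication group added as
nodes); centrality/bridge/pathway reports; bootstrap stability; and the
medication-group severity contrast.  Every artifact is written under the
output directory and recorded, with a SHA-256 hash, in ``manifest.json`` --
the same config and seed reproduce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    CONTINUOUS,
    CohortDataset,
    VariableSpec,
    read_dataset,
    write_network,
    write_table,
)
from .exceptions import PsychnetError, SpecError
from .groups import kruskal_wallis_bonferroni
from .metrics import centrality, pathway_subnetwork, select_domains
from .mgm import EstimationConfig, estimate_network, estimate_with_covariates
from .preprocess import npn_transform
from .robustness import StabilityConfig, case_drop_bootstrap, edge_ci_bootstrap
from .simulate import GeneratorConfig, generate_cohort, summarize_cohort

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Configuration of one full study run.

    Either ``data_path``+``spec_path`` (a real cohort) or ``preset`` (a
    synthetic one) must be given.  ``symptom_community`` names the symptom
    scale; every other non-covariate community is treated as a factor
    domain.  ``covariate_nodes`` are appended to the integrated networks in
    the adjusted reruns.
    """

    out_dir: str = "study_out"
    data_path: str | None = None
    spec_path: str | None = None
    preset: str | None = "paper_like"
    n: int = 791
    seed: int = 1
    npn_mode: str = "skewed"
    symptom_community: str = "ISI"
    total_score_node: str = "ISI_total"
    covariate_nodes: tuple[str, ...] = ("HAMD14", "medication")
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    run_stability: bool = True
    edge_ci_boot: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        est = EstimationConfig(**raw.pop("estimation", {}))
        stab = StabilityConfig(**raw.pop("stability", {}))
        if "covariate_nodes" in raw:
            raw["covariate_nodes"] = tuple(raw["covariate_nodes"])
        return cls(estimation=est, stability=stab, **raw)


def _load(config: StudyConfig) -> CohortDataset:
    if config.data_path:
        if not config.spec_path:
            raise SpecError("spec_path required with data_path")
        return read_dataset(config.data_path, config.spec_path)
    if not config.preset:
        raise SpecError("either data_path or preset must be set")
    data, _ = generate_cohort(GeneratorConfig(n=config.n, seed=config.seed, preset=config.preset))
    return data


def _with_total_score(data: CohortDataset, symptom_items: list[str], node: str) -> CohortDataset:
    total = data.values[symptom_items].sum(axis=1)
    spec = VariableSpec(node, CONTINUOUS, community=data.spec(symptom_items[0]).community,
                        role="symptom")
    values = data.values.drop(columns=symptom_items).copy()
    values.insert(0, node, total)
    specs = [spec] + [s for s in data.specs if s.name not in symptom_items]
    return CohortDataset(values, specs, provenance=data.provenance + ":total")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: StudyConfig) -> dict:
    """Execute the staged study; returns the manifest dictionary.

    Any stage failure aborts with the stage name; artifacts written before
    the failure stay on disk and the manifest carries a FAILED marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "estimation": vars(config.estimation).copy(),
        "stability": {**vars(config.stability), "drop_proportions": list(config.stability.drop_proportions)},
        "stages": [],
        "networks": {},
        "artifacts": {},
        "status": "RUNNING",
    }
    t_start = time.time()

    def artifact(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    def stage(name):
        manifest["stages"].append({"stage": name, "t": round(time.time() - t_start, 3)})
        logger.info("stage: %s", name)

    current = "setup"
    try:
        current = "load"
        stage(current)
        data = _load(config)
        manifest["n"] = data.n
        manifest["provenance"] = data.provenance

        current = "descriptives"
        stage(current)
        desc = summarize_cohort(data)
        write_table(desc.numeric, out / "descriptives_numeric.tsv")
        artifact("descriptives_numeric", out / "descriptives_numeric.tsv")
        if len(desc.categorical):
            write_table(desc.categorical, out / "descriptives_categorical.tsv")
            artifact("descriptives_categorical", out / "descriptives_categorical.tsv")

        current = "transform"
        stage(current)
        rep = npn_transform(data, mode=config.npn_mode)
        tdata = rep.transformed
        manifest["npn_columns"] = rep.columns_transformed

        comm_of = tdata.communities
        symptoms = [s.name for s in tdata.specs if s.community == config.symptom_community]
        if not symptoms:
            raise SpecError(f"no columns in symptom community {config.symptom_community!r}")
        covariate_cols = [s.name for s in tdata.specs if s.role == "covariate"]
        domains = sorted({s.community for s in tdata.specs
                          if s.role == "factor" and s.community != config.symptom_community})

        networks: dict[str, object] = {}

        def estimate(name, columns, covariates=None):
            sub = tdata.subset(columns)
            if covariates:
                net = estimate_with_covariates(sub, covariates, config.estimation)
            else:
                net = estimate_network(sub, config.estimation)
            networks[name] = net
            write_network(net, out / f"network_{name}.tsv")
            artifact(f"network_{name}", out / f"network_{name}.tsv")
            write_table(centrality(net), out / f"centrality_{name}.tsv")
            artifact(f"centrality_{name}", out / f"centrality_{name}.tsv")
            manifest["networks"][name] = {"nodes": net.p, "edges": net.n_edges()}
            return net

        current = "network:insomnia_only"
        stage(current)
        estimate("insomnia_only", symptoms)

        domain_nets = {}
        for dom in domains:
            current = f"network:insomnia_{dom}"
            stage(current)
            cols = symptoms + [s.name for s in tdata.specs if s.community == dom]
            domain_nets[dom] = estimate(f"insomnia_{dom}", cols)

        current = "screening"
        stage(current)
        retained = select_domains(domain_nets, config.symptom_community)
        manifest["domains"] = {"all": domains, "retained": retained}

        retained_cols = [s.name for s in tdata.specs if s.community in retained]

        current = "network:integrated_items"
        stage(current)
        integrated = estimate("integrated_items", symptoms + retained_cols)

        current = "network:integrated_total"
        stage(current)
        total_data = _with_total_score(
            tdata.subset(symptoms + retained_cols), symptoms, config.total_score_node
        )
        net_total = estimate_network(total_data, config.estimation)
        networks["integrated_total"] = net_total
        write_network(net_total, out / "network_integrated_total.tsv")
        artifact("network_integrated_total", out / "network_integrated_total.tsv")
        write_table(centrality(net_total), out / "centrality_integrated_total.tsv")
        artifact("centrality_integrated_total", out / "centrality_integrated_total.tsv")
        manifest["networks"]["integrated_total"] = {"nodes": net_total.p, "edges": net_total.n_edges()}

        covs = [c for c in config.covariate_nodes if c in tdata.names]
        if covs:
            current = "network:integrated_items_cov"
            stage(current)
            estimate("integrated_items_cov", symptoms + retained_cols + covs, covariates=covs)

            current = "network:integrated_total_cov"
            stage(current)
            cov_total = _with_total_score(
                tdata.subset(symptoms + retained_cols + covs), symptoms, config.total_score_node
            )
            net_tc = estimate_with_covariates(cov_total, covs, config.estimation)
            networks["integrated_total_cov"] = net_tc
            write_network(net_tc, out / "network_integrated_total_cov.tsv")
            artifact("network_integrated_total_cov", out / "network_integrated_total_cov.tsv")
            write_table(centrality(net_tc), out / "centrality_integrated_total_cov.tsv")
            artifact("centrality_integrated_total_cov", out / "centrality_integrated_total_cov.tsv")
            manifest["networks"]["integrated_total_cov"] = {"nodes": net_tc.p, "edges": net_tc.n_edges()}

        current = "pathways"
        stage(current)
        paths = pathway_subnetwork(integrated, retained_cols, symptoms)
        path_rows = [
            {"source": r.source, "target": r.target, "exists": r.exists,
             "distance": r.total_distance, "path": "->".join(r.path)}
            for r in paths.pathways
        ]
        ptab = pd.DataFrame(path_rows).set_index(["source", "target"])
        write_table(ptab, out / "pathways_integrated_items.tsv")
        artifact("pathways", out / "pathways_integrated_items.tsv")
        manifest["path_intermediaries"] = sorted(paths.intermediaries)

        if config.run_stability:
            current = "stability"
            stage(current)
            rep_s = case_drop_bootstrap(tdata.subset(symptoms + retained_cols),
                                        config.estimation, config.stability)
            cs_tab = pd.DataFrame({"cs": rep_s.cs}).rename_axis("index")
            write_table(cs_tab, out / "cs_coefficients.tsv")
            artifact("cs_coefficients", out / "cs_coefficients.tsv")
            manifest["cs"] = rep_s.cs

            current = "edge_ci"
            stage(current)
            ci = edge_ci_bootstrap(tdata.subset(symptoms + retained_cols),
                                   config.estimation, n_boot=config.edge_ci_boot,
                                   seed=config.stability.seed)
            write_table(ci, out / "edge_ci_integrated_items.tsv")
            artifact("edge_ci", out / "edge_ci_integrated_items.tsv")

        if "HAMD14" in data.names and "medication" in data.names:
            current = "group_comparison"
            stage(current)
            res = kruskal_wallis_bonferroni(
                data.values["HAMD14"].to_numpy(), data.values["medication"].to_numpy()
            )
            write_table(res.posthoc, out / "group_comparison_posthoc.tsv")
            artifact("group_comparison", out / "group_comparison_posthoc.tsv")
            manifest["group_comparison"] = {"H": res.H, "df": res.df, "p": res.p}

        manifest["status"] = "OK"
    except PsychnetError as exc:
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


__all__ = ["StudyConfig", "run_study"]
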