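"""End-to-end pipeline orchestration from a single config.

Stage order: simulate -> abundance -> diversity -> difftest -> mgs ->
cag -> annotate -> classify.  Every stage consumes only files written by
earlier stages (or listed inputs), all randomness derives from the
global seed, and a manifest records parameters, output paths and sha256
hashes, so re-running one config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, cag, classifier, differential, diversity, io, mgs, synthetic
from .clusters import cluster_matrix, membership_frame
from .taxonomy import annotate_clusters

log = logging.getLogger("quantmeta")

ALL_STAGES = ["simulate", "abundance", "diversity", "difftest",
              "mgs", "cag", "annotate", "classify"]

DEFAULT_CONFIG = {
    "schema_version": 1,
    "seed": 0,
    "stages": ALL_STAGES,
    "simulate": {
        "n_genomes": 6, "length_range": [10_000, 20_000], "shared_fraction": 0.1,
        "n_read_pairs": 20_000, "cohort": {},
    },
    "diversity": {"depth": 50_000},
    "difftest": {"floor_gene": 1e-7, "fdr_gene": 1e-3, "fdr_ko": 5e-3,
                 "ko_score": 60},
    "mgs": {"t1": 0.9, "min_size": 25, "t2": 0.8},
    "cag": {"t1p": 0.95, "t1s": 0.7, "t2": 0.9, "min_samples": 10,
            "floor_cag": 1e-8, "fdr_cag": 5e-4,
            "group_corr": 0.9, "group_fraction": 0.7,
            "big_cag": 700, "small_cag": 100},
    "annotate": {"consensus": 0.9, "match_id": 0.95, "match_cov": 0.9},
    "classify": {"step_gene": 5, "step_cluster": 1, "top_genes": 100},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = path_or_dict or {}
    return _merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % 2**31


class PipelineRun:
    def __init__(self, config: dict, out_dir):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"config": config, "stages": []}

    def path(self, name: str) -> Path:
        return self.out / name

    # ---- stages -----------------------------------------------------

    def stage_simulate(self):
        p = self.config["simulate"]
        seed = _stage_seed(self.config["seed"], "simulate")
        refs = synthetic.generate_references(
            p["n_genomes"], tuple(p["length_range"]), p["shared_fraction"], seed=seed)
        comp = np.random.default_rng(seed).dirichlet(np.ones(p["n_genomes"]))
        hits, origins = synthetic.simulate_hit_table(refs, comp, p["n_read_pairs"],
                                                     seed=seed + 1)
        spec = replace(synthetic.CohortSpec(), **p["cohort"], seed=seed + 2)
        (disc, val) = synthetic.generate_paired_cohorts(spec)
        (m_d, lab_d, truth), (m_v, lab_v, _) = disc, val
        mt = synthetic.generate_match_table(truth, seed=seed + 3)
        ko = synthetic.generate_ko_table(m_d.index, seed=seed + 4)

        io.write_lengths(refs.lengths, self.path("genome_lengths.tsv"))
        io.write_hit_table(hits, self.path("hits.tsv"))
        origins.rename("genome").to_frame().to_csv(
            self.path("true_origins.tsv"), sep="\t", index_label="read_id")
        io.write_abundance_matrix(m_d, self.path("discovery_abundance.tsv"))
        io.write_labels(lab_d, self.path("discovery_labels.tsv"))
        io.write_abundance_matrix(m_v, self.path("validation_abundance.tsv"))
        io.write_labels(lab_v, self.path("validation_labels.tsv"))
        io.write_truth(truth, self.path("truth.json"))
        io.write_match_table(mt, self.path("matches.tsv"))
        ko.to_csv(self.path("ko_scores.tsv"), sep="\t", index=False)
        return ["genome_lengths.tsv", "hits.tsv", "true_origins.tsv",
                "discovery_abundance.tsv", "discovery_labels.tsv",
                "validation_abundance.tsv", "validation_labels.tsv",
                "truth.json", "matches.tsv", "ko_scores.tsv"]

    def stage_abundance(self):
        hits = io.read_hit_table(self.path("hits.tsv"))
        lengths = io.read_lengths(self.path("genome_lengths.tsv"))
        ab = abundance.species_abundance(hits, lengths)
        rel = abundance.normalize_relative(ab)
        pd.DataFrame({"abundance": ab, "relative": rel}).to_csv(
            self.path("species_abundance.tsv"), sep="\t", index_label="genome")
        return ["species_abundance.tsv"]

    def stage_diversity(self):
        m = io.read_abundance_matrix(self.path("discovery_abundance.tsv"))
        seed = _stage_seed(self.config["seed"], "diversity")
        table = diversity.diversity_table(m, depth=self.config["diversity"]["depth"],
                                          seed=seed)
        table.to_csv(self.path("diversity.tsv"), sep="\t")
        return ["diversity.tsv"]

    def stage_difftest(self):
        p = self.config["difftest"]
        m = io.read_abundance_matrix(self.path("discovery_abundance.tsv"))
        labels = io.read_labels(self.path("discovery_labels.tsv"))
        res, pi0 = differential.differential_test(m, labels,
                                                  floor=p["floor_gene"],
                                                  fdr=p["fdr_gene"])
        res.to_csv(self.path("diff_genes.tsv"), sep="\t", index_label="feature")
        ko_scores = pd.read_csv(self.path("ko_scores.tsv"), sep="\t")
        ko_matrix = differential.aggregate_ko(m, ko_scores, min_score=p["ko_score"])
        outputs = ["diff_genes.tsv"]
        if len(ko_matrix) >= 2:
            ko_res, _ = differential.differential_test(
                ko_matrix, labels, floor=0.0, fdr=p["fdr_ko"])
            ko_res.to_csv(self.path("diff_kos.tsv"), sep="\t", index_label="feature")
            outputs.append("diff_kos.tsv")
        self.manifest.setdefault("metrics", {})["pi0_genes"] = pi0
        return outputs

    def _significant_genes(self) -> list:
        res = pd.read_csv(self.path("diff_genes.tsv"), sep="\t", index_col=0)
        return res.index[res["significant"]].tolist()

    def stage_mgs(self):
        p = self.config["mgs"]
        m = io.read_abundance_matrix(self.path("discovery_abundance.tsv"))
        genes = self._significant_genes()
        clusters = mgs.identify_mgs(m.loc[genes], stage1_threshold=p["t1"],
                                    min_size=p["min_size"], stage2_threshold=p["t2"])
        membership_frame(clusters).to_csv(self.path("mgs_membership.tsv"),
                                          sep="\t", index=False)
        if clusters:
            cluster_matrix(clusters, m).to_csv(self.path("mgs_profiles.tsv"),
                                               sep="\t", index_label="cluster")
            return ["mgs_membership.tsv", "mgs_profiles.tsv"]
        return ["mgs_membership.tsv"]

    def stage_cag(self):
        p = self.config["cag"]
        m = io.read_abundance_matrix(self.path("discovery_abundance.tsv"))
        labels = io.read_labels(self.path("discovery_labels.tsv"))
        clusters = cag.cag_pipeline(m, min_samples=p["min_samples"],
                                    t1_pearson=p["t1p"], t1_spearman=p["t1s"],
                                    t2_pearson=p["t2"],
                                    group_corr=p["group_corr"],
                                    group_fraction=p["group_fraction"])
        membership_frame(clusters).to_csv(self.path("cag_membership.tsv"),
                                          sep="\t", index=False)
        outputs = ["cag_membership.tsv"]
        if clusters:
            cluster_matrix(clusters, m).to_csv(self.path("cag_profiles.tsv"),
                                               sep="\t", index_label="cluster")
            markers, _ = cag.cag_marker_test(clusters, m, labels,
                                             floor=p["floor_cag"], fdr=p["fdr_cag"])
            markers.to_csv(self.path("cag_markers.tsv"), sep="\t",
                           index_label="cluster")
            outputs += ["cag_profiles.tsv", "cag_markers.tsv"]
        return outputs

    def _load_clusters(self):
        from .clusters import GeneCluster

        clusters = []
        for name in ("mgs_membership.tsv", "cag_membership.tsv"):
            f = self.path(name)
            if not f.exists():
                continue
            df = pd.read_csv(f, sep="\t")
            for cid, grp in df.groupby("cluster"):
                clusters.append(GeneCluster(cluster_id=cid,
                                            genes=sorted(grp["gene"]),
                                            kind=grp["kind"].iloc[0]))
        return clusters

    def stage_annotate(self):
        p = self.config["annotate"]
        mt = io.read_match_table(self.path("matches.tsv"))
        from .taxonomy import filter_valid_matches

        mt = filter_valid_matches(mt, p["match_id"], p["match_cov"])
        ann = annotate_clusters(self._load_clusters(), mt,
                                consensus=p["consensus"], prefiltered=True)
        ann.to_csv(self.path("annotations.tsv"), sep="\t")
        return ["annotations.tsv"]

    def stage_classify(self):
        p = self.config["classify"]
        m_d = io.read_abundance_matrix(self.path("discovery_abundance.tsv"))
        lab_d = io.read_labels(self.path("discovery_labels.tsv"))
        m_v = io.read_abundance_matrix(self.path("validation_abundance.tsv"))
        lab_v = io.read_labels(self.path("validation_labels.tsv"))

        outputs = []
        modes = {}
        res = pd.read_csv(self.path("diff_genes.tsv"), sep="\t", index_col=0)
        top = res.nsmallest(p["top_genes"], "p").index.tolist()
        if top:
            modes["gene"] = (m_d.loc[top], m_v.loc[top], p["step_gene"])
        clusters = self._load_clusters()
        if clusters:
            modes["cluster"] = (cluster_matrix(clusters, m_d),
                                cluster_matrix(clusters, m_v), p["step_cluster"])

        auc_summary = {}
        for mode, (x_d, x_v, step) in modes.items():
            panel = classifier.select_best_subset(x_d, lab_d, step=step,
                                                  feature_kind=mode)
            panel = classifier.train_and_roc(panel, x_d, lab_d, x_v, lab_v)
            pd.DataFrame({"feature": panel.selected}).to_csv(
                self.path(f"panel_{mode}.tsv"), sep="\t", index=False)
            pd.Series(panel.mcc_trace, name="mcc").rename_axis("subset_size") \
                .to_frame().to_csv(self.path(f"mcc_trace_{mode}.tsv"), sep="\t")
            classifier.roc_frame(panel).to_csv(self.path(f"roc_{mode}.tsv"),
                                               sep="\t", index=False)
            auc_summary[mode] = panel.auc
            outputs += [f"panel_{mode}.tsv", f"mcc_trace_{mode}.tsv", f"roc_{mode}.tsv"]
        self.path("auc_summary.json").write_text(
            json.dumps(auc_summary, indent=1, sort_keys=True))
        return outputs + ["auc_summary.json"]

    # ---- driver -----------------------------------------------------

    def run(self) -> dict:
        for stage in self.config["stages"]:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage: {stage}")
            fn = getattr(self, f"stage_{stage}")
            log.info("stage %s", stage)
            try:
                outputs = fn()
            except Exception as exc:
                for f in self.out.glob("*.tmp"):
                    f.rename(f.with_suffix(f.suffix + ".partial"))
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            self.manifest["stages"].append({
                "name": stage,
                "parameters": self.config.get(stage, {}),
                "outputs": {f: _sha256(self.path(f)) for f in outputs},
            })
        manifest_path = self.path("manifest.json")
        manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True,
                                            default=str))
        return self.manifest


def run_pipeline(config, out_dir) -> dict:
    """Execute the configured stages; returns the manifest."""
    return PipelineRun(load_config(config), out_dir).run()
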