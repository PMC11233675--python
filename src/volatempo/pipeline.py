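"""Configuration and the end-to-end pipeline driver.

Chains simulate -> deconvolve -> filter -> asca -> cluster -> kinetics per
stage toggles, with a named random stream per stage derived from the global
seed, and writes every artifact (tables, reports, envelopes, resolved
config, run log) under one output directory.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .annotate import annotate_components, build_peak_table
from .parafac2 import select_components, fit_parafac2
from .preprocess import consistency_filter, cv_filter, scale_matrix
from .profiling import (cut_tree, kinetic_summary, pca_samples,
                        temporal_profile_matrix, ward_cluster)
from .rmasca import RMASCA
from .simulate import (NoiseModel, library_from_factors, make_design,
                       simulate_alkane_ladder, simulate_peak_table,
                       simulate_spectral_library, simulate_tensor,
                       study_templates)

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_CONFIG"]

logger = logging.getLogger("volatempo")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "volatempo_out",
    "stages": {
        "simulate": True,
        "deconvolve": True,
        "filter": True,
        "asca": True,
        "cluster": True,
        "kinetics": True,
    },
    "simulate": {
        "groups": ["I", "O", "FM", "SM"],
        "time_points_h": [0, 4, 8, 12, 16, 20, 24],
        "replicates": 3,
        "n_compounds": 88,
        "multiplicative_cv": 0.15,
        "additive_sd": 2.0,
        "missing_below": 1.0,
        "library_decoys": 20,
        "tensor": {
            "n_scans": 100,
            "mz_min": 35,
            "mz_max": 110,
            "n_samples": 12,
            "n_components": 3,
            "shift_range_scans": 5,
            "snr_db": 20.0,
        },
    },
    "deconvolve": {
        "f_max": 4,
        "n_restarts": 4,
        "corcondia_threshold": 80.0,
        "fit_tolerance_pp": 0.5,
        "min_score": 0.6,
    },
    "filter": {"cv_threshold": 0.05},
    "asca": {
        "groups": ["I", "O", "FM"],
        "scaling": "unit-sd",
        "n_components": 3,
        "resamples": 200,
        "level": 0.95,
        "top_k": 12,
    },
    "cluster": {"k_major": 2, "k_sub": 4, "standardize": True},
    "kinetics": {"group": "O", "plateau_tol": 0.05},
    "inputs": {"peak_table": None, "tensor_dir": None, "library": None},
}


@dataclasses.dataclass
class PipelineConfig:
    """Fully resolved pipeline configuration.

    Built from defaults overlaid with a user dict or YAML file; unknown keys
    are rejected so silent typos cannot change a run.  Every run writes its
    resolved config next to its outputs.
    """

    settings: dict

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls(copy.deepcopy(DEFAULT_CONFIG))

    @classmethod
    def from_dict(cls, overrides: dict) -> "PipelineConfig":
        settings = copy.deepcopy(DEFAULT_CONFIG)
        _merge(settings, overrides, path="")
        return cls(settings)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        return cls.from_dict(overrides)

    def __getitem__(self, key):
        return self.settings[key]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.settings, fh, sort_keys=False)


def _merge(base: dict, overrides: dict, path: str) -> None:
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ValueError(f"unknown configuration key: {here!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            _merge(base[key], value, here)
        else:
            base[key] = value


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig | dict | None = None) -> dict:
    """Execute the configured stages; returns a dict of artifact paths.

    Stage dependencies are explicit: a stage that needs a peak table uses
    the simulated one unless ``inputs.peak_table`` points at a file; asking
    for a downstream stage with neither is an error.
    """
    if config is None:
        config = PipelineConfig.default()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    cfg = config.settings
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    artifacts: dict = {}
    try:
        config.to_yaml(outdir / "config_resolved.yaml")
        artifacts["config"] = outdir / "config_resolved.yaml"
        stages = cfg["stages"]
        table = None
        tensor = None
        library = None

        if stages["simulate"]:
            logger.info("stage simulate: start")
            sc = cfg["simulate"]
            design = make_design(groups=sc["groups"],
                                 time_points_h=sc["time_points_h"],
                                 replicates=sc["replicates"])
            templates, class_map = study_templates(design, sc["n_compounds"],
                                                   seed=seed)
            noise = NoiseModel(multiplicative_cv=sc["multiplicative_cv"],
                               additive_sd=sc["additive_sd"],
                               missing_below=sc["missing_below"])
            table, truth = simulate_peak_table(design, templates, noise,
                                               seed=seed)
            vio.write_peak_table(table, outdir / "peak_table.csv")
            truth.to_json(outdir / "ground_truth.json")
            with open(outdir / "compound_classes.json", "w") as fh:
                json.dump(class_map, fh, indent=2)
            tc = sc["tensor"]
            tensor, true_factors = simulate_tensor(
                n_scans=tc["n_scans"],
                mz_axis=np.arange(tc["mz_min"], tc["mz_max"] + 1),
                n_samples=tc["n_samples"],
                n_components=tc["n_components"],
                shift_range_scans=tc["shift_range_scans"],
                noise_snr_db=tc["snr_db"], seed=seed,
            )
            vio.write_tensor_dir(tensor, outdir / "tensor")
            names = [f"tensor_compound_{f}" for f in range(tc["n_components"])]
            library = library_from_factors(true_factors, tensor.mz_axis, names)
            library += simulate_spectral_library(
                sc["library_decoys"], mz_axis=tensor.mz_axis, seed=seed
            )
            vio.write_msp(library, outdir / "library.msp")
            ladder = simulate_alkane_ladder()
            pd.DataFrame(ladder, columns=["carbon_number", "retention_time_min"]
                         ).to_csv(outdir / "alkane_ladder.csv", index=False)
            artifacts.update(
                peak_table=outdir / "peak_table.csv",
                tensor_dir=outdir / "tensor",
                library=outdir / "library.msp",
                alkane_ladder=outdir / "alkane_ladder.csv",
            )
            logger.info("stage simulate: wrote %d-compound table, tensor, library",
                        sc["n_compounds"])

        if cfg["inputs"]["peak_table"]:
            table = vio.read_peak_table(cfg["inputs"]["peak_table"])
        if cfg["inputs"]["tensor_dir"]:
            tensor = vio.read_tensor_dir(cfg["inputs"]["tensor_dir"])
        if cfg["inputs"]["library"]:
            library = vio.read_msp(cfg["inputs"]["library"])

        if stages["deconvolve"]:
            if tensor is None:
                raise ValueError("deconvolve requested but no tensor available "
                                 "(enable simulate or set inputs.tensor_dir)")
            logger.info("stage deconvolve: start")
            dc = cfg["deconvolve"]
            report = select_components(
                tensor, dc["f_max"],
                fit_tolerance_pp=dc["fit_tolerance_pp"],
                corcondia_threshold=dc["corcondia_threshold"],
                seed=seed, n_restarts=dc["n_restarts"],
            )
            report.to_json(outdir / "model_selection.json")
            results = fit_parafac2(tensor, report.chosen_F, seed=seed,
                                   n_restarts=dc["n_restarts"])
            with open(outdir / "parafac2_summary.txt", "w") as fh:
                fh.write(results.summary() + "\n")
            if library is not None:
                anns = annotate_components(results, library,
                                           min_score=dc["min_score"])
                pd.DataFrame([dataclasses.asdict(a) for a in anns]).to_csv(
                    outdir / "annotations.csv", index=False
                )
                artifacts["annotations"] = outdir / "annotations.csv"
            artifacts["model_selection"] = outdir / "model_selection.json"
            logger.info("stage deconvolve: chose F=%d (reliable=%s)",
                        report.chosen_F, report.reliable)

        filtered = table
        if stages["filter"]:
            if table is None:
                raise ValueError("filter requested but no peak table available")
            logger.info("stage filter: start")
            filtered, rep1 = consistency_filter(table)
            filtered, rep2 = cv_filter(filtered, cfg["filter"]["cv_threshold"])
            rep1.to_json(outdir / "filter_consistency.json")
            rep2.to_json(outdir / "filter_cv.json")
            vio.write_peak_table(filtered, outdir / "peak_table_filtered.csv")
            artifacts["peak_table_filtered"] = outdir / "peak_table_filtered.csv"
            logger.info("stage filter: %d -> %d -> %d compounds",
                        rep1.n_before, rep1.n_after, rep2.n_after)

        if stages["asca"]:
            if filtered is None:
                raise ValueError("asca requested but no peak table available")
            logger.info("stage asca: start")
            ac = cfg["asca"]
            sub = filtered[filtered["group"].isin(ac["groups"])]
            if sub.empty:
                raise ValueError(f"asca groups {ac['groups']} not in table")
            scaled = scale_matrix(sub, method=ac["scaling"])
            model = RMASCA(scaled, n_components=ac["n_components"])
            fit = model.fit()
            with open(outdir / "asca_summary.txt", "w") as fh:
                fh.write(fit.summary() + "\n")
            sca = fit.sca_for("combined")
            sca.loadings.to_csv(outdir / "asca_loadings.csv")
            sca.trajectories.to_csv(outdir / "asca_scores.csv", index=False)
            env = fit.bootstrap(n_resamples=ac["resamples"], level=ac["level"],
                                seed=seed)
            env.score_ci.to_csv(outdir / "asca_score_envelopes.csv", index=False)
            env.loading_ci.to_csv(outdir / "asca_loading_envelopes.csv",
                                  index=False)
            k = min(ac["top_k"], sca.loadings.shape[0])
            fit.rank_loadings(component=1, k=k).to_csv(
                outdir / "asca_top_loadings.csv", index=False
            )
            report = {
                "engine": fit.engine,
                "explained_pct": {
                    e: (None if fit.sca[e] is None
                        else fit.sca[e].explained_pct.tolist())
                    for e in fit.sca
                },
                "n_resamples": env.n_resamples,
                "unmatched_components": env.n_unmatched_components,
            }
            with open(outdir / "asca_report.json", "w") as fh:
                json.dump(report, fh, indent=2)
            artifacts.update(
                asca_scores=outdir / "asca_scores.csv",
                asca_loadings=outdir / "asca_loadings.csv",
                asca_score_envelopes=outdir / "asca_score_envelopes.csv",
                asca_report=outdir / "asca_report.json",
            )
            logger.info("stage asca: PC1 %.2f%% explained",
                        sca.explained_pct[0])

        if stages["cluster"]:
            if filtered is None:
                raise ValueError("cluster requested but no peak table available")
            logger.info("stage cluster: start")
            cc = cfg["cluster"]
            profiles = temporal_profile_matrix(filtered,
                                               standardize=cc["standardize"])
            clustering = ward_cluster(profiles, axis=0)
            clustering.to_json(outdir / "cluster_tree.json")
            assignments = pd.DataFrame(
                {
                    "compound": clustering.labels,
                    "major_cluster": cut_tree(clustering, cc["k_major"]).to_numpy(),
                    "sub_cluster": cut_tree(clustering, cc["k_sub"]).to_numpy(),
                }
            )
            assignments.to_csv(outdir / "cluster_assignments.csv", index=False)
            scaled_all = scale_matrix(filtered)
            pca = pca_samples(scaled_all.values, n_components=2)
            scores = pca.scores.copy()
            scores.index.name = "sample_id"
            scores = scores.reset_index().merge(scaled_all.row_meta,
                                                on="sample_id")
            scores.to_csv(outdir / "pca_sample_scores.csv", index=False)
            artifacts.update(
                cluster_tree=outdir / "cluster_tree.json",
                cluster_assignments=outdir / "cluster_assignments.csv",
                pca_scores=outdir / "pca_sample_scores.csv",
            )
            logger.info("stage cluster: %d compounds into %d sub-clusters",
                        len(clustering.labels), cc["k_sub"])

        if stages["kinetics"]:
            if filtered is None:
                raise ValueError("kinetics requested but no peak table available")
            logger.info("stage kinetics: start")
            kc = cfg["kinetics"]
            ks = kinetic_summary(filtered, group=kc["group"],
                                 plateau_tol=kc["plateau_tol"])
            ks.curves.to_csv(outdir / f"kinetics_curves_{kc['group']}.csv",
                             index=False)
            ks.summary.to_csv(outdir / f"kinetics_summary_{kc['group']}.csv",
                              index=False)
            artifacts["kinetics_summary"] = (
                outdir / f"kinetics_summary_{kc['group']}.csv"
            )
            logger.info("stage kinetics: %d compounds summarised",
                        len(ks.summary))
        logger.info("pipeline complete")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {k: str(v) for k, v in artifacts.items()}
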