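"""End-to-end orchestration: simulate (or load) the six input tables,
run every analysis stage, and emit one consolidated JSON report.

Stage order mirrors the analysis: features -> conservation -> pathway
classes/layers -> PPI resampling -> mutation profiles.  Per-stage seeds
are derived from one master seed through stable per-stage hashing, so
toggling one stage never perturbs another's randomness; identical
config + seed yields an identical report (timestamps live only in the
manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import conservation as cons
from . import interaction_resampling as ppi
from . import mutation_profiles as mut
from . import pathway_layers as pl
from . import proteomics_features as pf
from . import synthetic_data as syn
from .stats_core import ComparisonResult, correlation

__all__ = ["RunConfig", "run_all", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, independent across stages."""
    h = zlib.crc32(stage.encode())
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of a full run.

    Either ``simulate`` holds WorldConfig overrides (synthetic inputs
    are generated into ``outdir``) or ``inputs`` names the six existing
    tables (intensities, homology, tree, pathways, edges, mutations).
    """

    outdir: str = "bowtievar_run"
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    alpha: float = 0.01
    min_detect: float = 0.5
    log10: bool = True
    n_pairs: int = 1000
    feature_bins: int = 5
    mutation_bins: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.simulate is None and self.inputs is None:
            self.simulate = {}
        if self.simulate is not None and self.inputs is not None:
            raise ValueError("provide either a simulate block or inputs, not both")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, ComparisonResult):
        return obj.as_dict()
    if isinstance(obj, mut.BinnedProfile):
        return obj.as_dict()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonify(v) for v in sorted(obj) if True] if isinstance(obj, (set, frozenset)) \
            else [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj]
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    return obj


def _load_inputs(config: RunConfig, outdir: Path):
    if config.simulate is not None:
        overrides = dict(config.simulate)
        overrides.setdefault("seed", stage_seed(config.seed, "simulate"))
        wc = syn.WorldConfig(**overrides)
        world = syn.generate_world(wc)
        syn.write_world(world, outdir / "inputs")
        return (world.intensities, world.homology, world.tree, world.pathways,
                world.edges, world.mutations)
    paths = config.inputs
    intensities = pf.IntensityMatrix.read_tsv(paths["intensities"])
    homology = cons.read_homology_tsv(paths["homology"])
    tree = cons.read_newick(paths["tree"])
    pathways = pd.read_csv(paths["pathways"], sep="\t", dtype=str)
    edges = ppi.EdgeList.read_tsv(paths["edges"])
    mutations = mut.read_mutations_tsv(paths["mutations"])
    return intensities, homology, tree, pathways, edges, mutations


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    try:
        intensities, homology, tree, pathways, edges, mutations = _load_inputs(
            config, outdir)
    except Exception as exc:
        raise RuntimeError(f"stage 'load_inputs' failed: {exc}") from exc

    # -- proteomics features ------------------------------------------
    try:
        features = pf.compute_features(intensities, min_detect=config.min_detect,
                                       log_transform=config.log10)
        raw_sd = pf.raw_protein_sd(intensities, log_transform=config.log10)
        confound = pf.confound_check(features, raw_sd)
        features.to_csv(outdir / "features.tsv", sep="\t", float_format="%.10g")
        report["stages"]["features"] = {
            "n_input_proteins": int(len(intensities.values)),
            "n_after_detection_filter": int(len(features)),
            "n_f_defined": int(np.isfinite(features["log10_f"]).sum()),
            "confound": {k: v.as_dict() for k, v in confound.items()},
        }
        logger.info("features: %d proteins in, %d pass detection filter",
                    len(intensities.values), len(features))
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc

    # -- conservation --------------------------------------------------
    try:
        scores = cons.conservation_scores(tree, homology)
        cons.write_scores_tsv(scores, outdir / "conservation.tsv")
        feat = features.join(scores["score"], how="left")
        fin = feat.dropna(subset=["score", "mean_abundance"])
        cons_abund = correlation(fin["score"], fin["mean_abundance"])
        finf = fin.dropna(subset=["log10_f"])
        cons_var = correlation(finf["score"], finf["log10_f"])
        report["stages"]["conservation"] = {
            "n_scored": int(len(scores)),
            "tree_length": float(tree.total_length),
            "score_vs_abundance": cons_abund.as_dict(),
            "score_vs_log_f": cons_var.as_dict(),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'conservation' failed: {exc}") from exc

    # -- pathway classes / layers --------------------------------------
    try:
        ann = pl.annotate(pathways)
        ann.to_csv(outdir / "layers.tsv", sep="\t")
        universe = set(ann.index) & set(feat.index)
        class_tests = {}
        for cls in sorted(set(ann["functional_class"]) - {"none", "ambiguous"}):
            members = set(ann.index[ann["functional_class"] == cls]) & universe
            if not members or len(members) == len(universe):
                continue
            class_tests[cls] = {
                f: pl.class_feature_test(feat[f], members, universe,
                                         alpha=config.alpha)
                for f in ("log10_f", "score", "mean_abundance")
                if feat[f].notna().any()
            }
        layer_summary = pl.layer_feature_summary(feat, ann, alpha=config.alpha)
        excl = pl.split_exclusive_multiple(pathways, feat, alpha=config.alpha)
        report["stages"]["layers"] = {
            "n_annotated": int(len(ann)),
            "n_ambiguous": int((ann["functional_class"] == "ambiguous").sum()),
            "layer_sizes": ann["layer"].value_counts().to_dict(),
            "class_tests": class_tests,
            "layer_summary": layer_summary,
            "exclusive_vs_multiple": {
                "n_exclusive": len(excl["exclusive"]),
                "n_multiple": len(excl["multiple"]),
                "comparisons": excl["comparisons"],
                "fold_over_expectation": excl["fold_over_expectation"],
            },
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'layers' failed: {exc}") from exc

    # -- PPI resampling ------------------------------------------------
    try:
        layers_series = ann["layer"]
        log_f = feat["log10_f"]
        seed = stage_seed(config.seed, "ppi")
        it = ppi.oriented_it_sample(edges, layers_series, log_f,
                                    n=config.n_pairs, seed=seed)
        dists = {"PPI-IT": ppi.abs_variability_diff(it)}
        for cat in ("PPI-TO", "PPI-W", "PPI-Rand", "Rand-IT"):
            s = ppi.sample_pairs(edges, layers_series, log_f, cat,
                                 n=config.n_pairs, seed=stage_seed(config.seed,
                                                                   f"ppi:{cat}"))
            dists[cat] = ppi.abs_variability_diff(s)
        perm = ppi.permute_links(it, seed=stage_seed(config.seed, "ppi:perm"))
        dists["Perm-IT"] = ppi.abs_variability_diff(perm)
        pd.DataFrame(dists).to_csv(outdir / "ppi_diffs.tsv", sep="\t",
                                   index=False, float_format="%.10g")
        comparisons = {
            f"PPI-IT_vs_{cat}": ppi.compare_pair_distributions(
                dists["PPI-IT"], dists[cat], alpha=config.alpha)
            for cat in ("PPI-TO", "PPI-W", "PPI-Rand", "Rand-IT", "Perm-IT")
        }
        report["stages"]["ppi"] = {
            "n_pairs": config.n_pairs,
            "medians": {cat: float(np.median(d)) for cat, d in dists.items()},
            "comparisons": comparisons,
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'ppi' failed: {exc}") from exc

    # -- mutation profiles ---------------------------------------------
    try:
        mut_feats = feat.rename(columns={"score": "conservation"})
        comparisons = {}
        for fname in ("conservation", "log10_f", "mean_abundance"):
            comparisons[fname] = mut.mutation_class_comparison(
                mut_feats, mutations, fname, alpha=config.alpha)
        profiles = {}
        for fname in ("conservation", "log10_f"):
            prof = mut.binned_mutation_profile(mut_feats, mutations, fname,
                                               k=config.mutation_bins)
            profiles[fname] = prof
            pd.DataFrame(prof.per_bin_mean).to_csv(
                outdir / f"mutation_profile_{fname}.tsv", sep="\t",
                float_format="%.10g")
        report["stages"]["mutations"] = {
            "carrier_comparisons": comparisons,
            "profiles": profiles,
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'mutations' failed: {exc}") from exc

    # -- report + manifest ---------------------------------------------
    report_json = _jsonify(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report_json, fh, indent=1, sort_keys=True)
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ("simulate", "ppi", "ppi:perm")},
        "timestamp": pd.Timestamp.now().isoformat(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report_json
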