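"""Synthetic world generator: six mutually consistent input tables with
planted, configurable statistical structure.

The generator emulates the inputs of the study — a multi-cell-line MS
intensity matrix with replicates, a homolog-presence table over a
weighted species tree, pathway/functional-class annotations, a PPI edge
list, and per-protein mutation counts — so that every downstream stage
of the pipeline can be tested as a parameter-recovery problem.

Planted structure
-----------------
* latent log10 abundance a_i ~ Normal(abundance_log_mean, abundance_log_sd);
* replicate noise sd sigma_i = replicate_noise_sd *
  10^(-noise_abundance_exponent * (a_i - abundance_log_mean)) — lowly
  abundant proteins are noisier, reproducing the technical confound of
  label-free MS;
* between-cell-line offsets have sd tau_i = between_cell_scale *
  sqrt(v_i) * sigma_i, where v_i = layer multiplier x lognormal spread.
  Planting the biological between-line dispersion on the same
  abundance-dependent scale as the noise means the variance *ratio* F
  recovers the layer multipliers free of the abundance confound — which
  is exactly the property the F statistic is designed to have;
* homolog retention per species is Bernoulli with a logistic
  probability increasing in abundance (slope
  ``conservation_abundance_effect``), shifted per layer
  (``layer_conservation_offsets``, bell-shaped by default: transmission
  most conserved) and decreasing with the species' tree distance from
  the reference;
* input-transmission PPI edges are variability-assortative: with
  probability ``wiring_assortativity`` an edge is rank-discordant — a
  shared latent pairs a top-stratum protein of one layer with a
  bottom-stratum protein of the other (antithetic within-layer
  variability ranks) — genuine within-pair coupling that the
  link-permutation control destroys while preserving the marginals;
* mutation counts are Poisson with per-conservation-bin rates
  (``mutation_profile_shapes``), making profile recovery a clean
  parameter-recovery test.

All randomness flows from ``WorldConfig.seed`` through per-stage
``numpy`` seed sequences: the same config yields byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import conservation as cons
from .interaction_resampling import EdgeList
from .pathway_layers import DEFAULT_PATHWAY_LABELS, quantile_bin
from .proteomics_features import IntensityMatrix

__all__ = [
    "ConfigError",
    "WorldConfig",
    "World",
    "generate_world",
    "generate_intensities",
    "write_world",
    "CELL_LINES",
    "NONHUMAN_SPECIES",
]

CELL_LINES = ["A549", "GAMG", "HEK293", "Hela", "HepG2", "Jurkat",
              "K562", "LnCap", "MCF7", "RKO", "U2OS"]

NONHUMAN_SPECIES = [
    "Pan_troglodytes", "Mus_musculus", "Rattus_norvegicus", "Gallus_gallus",
    "Danio_rerio", "Drosophila_melanogaster", "Anopheles_gambiae",
    "Caenorhabditis_elegans", "Schizosaccharomyces_pombe",
    "Saccharomyces_cerevisiae", "Eremothecium_gossypii",
    "Arabidopsis_thaliana", "Oryza_sativa",
]

LAYERS = ("input", "transmission", "output", "other")

TRANSMISSION_CLASSES = ["kinase", "phosphatase", "adaptor", "gtpase_binding",
                        "mediator", "cofactor"]


class ConfigError(ValueError):
    """Invalid WorldConfig."""


def _default_fractions() -> dict:
    return {"input": 0.25, "transmission": 0.35, "output": 0.15, "other": 0.25}


def _default_multipliers() -> dict:
    return {"input": 4.0, "transmission": 1.0, "output": 1.0, "other": 2.0}


def _default_cons_offsets() -> dict:
    return {"input": -0.8, "transmission": 1.5, "output": -0.8, "other": 0.0}


def _default_mutation_shapes() -> dict:
    # per-conservation-quintile Poisson rates; somatic peaks at high
    # conservation, germline at intermediate, SNP background decreasing
    return {
        "somatic": [0.2, 0.6, 1.2, 2.0, 1.2],
        "germline": [0.5, 1.4, 2.0, 1.0, 0.3],
        "snp": [2.2, 1.8, 1.4, 1.1, 0.9],
    }


@dataclass
class WorldConfig:
    n_proteins: int = 2000
    n_cell_lines: int = 11
    n_replicates_per_line: int = 3
    abundance_log_mean: float = 7.0
    abundance_log_sd: float = 1.0
    noise_abundance_exponent: float = 0.3
    replicate_noise_sd: float = 0.25
    between_cell_scale: float = 1.0
    within_layer_variability_sd: float = 1.0
    layer_fractions: Mapping[str, float] = field(default_factory=_default_fractions)
    layer_variability_multipliers: Mapping[str, float] = field(
        default_factory=_default_multipliers)
    layer_conservation_offsets: Mapping[str, float] = field(
        default_factory=_default_cons_offsets)
    conservation_abundance_effect: float = 0.8
    homology_base: float = 1.0
    homology_distance_scale: float = 2.5
    missing_fraction: float = 0.08
    wiring_assortativity: float = 0.8
    assortative_quantile: float = 0.05
    edges_per_protein: float = 4.0
    multi_pathway_fraction: float = 0.19
    multi_pathway_conservation_bias: float = 1.0
    ambiguous_fraction: float = 0.02
    n_pathways: int = 10
    mutation_profile_shapes: Mapping[str, list] = field(
        default_factory=_default_mutation_shapes)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_cell_lines", "n_replicates_per_line",
                     "n_pathways"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        fr = dict(self.layer_fractions)
        if set(fr) != set(LAYERS):
            raise ConfigError(f"layer_fractions must cover {LAYERS}")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ConfigError("layer_fractions must sum to 1 within 1e-9")
        if any(f < 0 for f in fr.values()):
            raise ConfigError("layer_fractions must be non-negative")
        mult = dict(self.layer_variability_multipliers)
        if set(mult) != set(LAYERS):
            raise ConfigError(f"layer_variability_multipliers must cover {LAYERS}")
        if any(m <= 0 for m in mult.values()):
            raise ConfigError("layer_variability_multipliers must be > 0")
        if not 0 <= self.wiring_assortativity <= 1:
            raise ConfigError("wiring_assortativity must be in [0, 1]")
        if not 0 <= self.missing_fraction < 1:
            raise ConfigError("missing_fraction must be in [0, 1)")
        if not 0 < self.assortative_quantile <= 0.5:
            raise ConfigError("assortative_quantile must be in (0, 0.5]")
        shapes = {k: list(v) for k, v in self.mutation_profile_shapes.items()}
        lens = {len(v) for v in shapes.values()}
        if len(lens) != 1 or min(lens) < 2:
            raise ConfigError("mutation_profile_shapes must be equal-length vectors (>=2 bins)")
        if any(r < 0 for v in shapes.values() for r in v):
            raise ConfigError("mutation rates must be non-negative")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["layer_fractions"] = dict(self.layer_fractions)
        d["layer_variability_multipliers"] = dict(self.layer_variability_multipliers)
        d["layer_conservation_offsets"] = dict(self.layer_conservation_offsets)
        d["mutation_profile_shapes"] = {k: list(v) for k, v in
                                        self.mutation_profile_shapes.items()}
        return d


@dataclass
class World:
    config: WorldConfig
    intensities: IntensityMatrix
    homology: dict[str, set[str]]
    tree: cons.SpeciesTree
    pathways: pd.DataFrame
    edges: EdgeList
    mutations: pd.DataFrame
    truth: pd.DataFrame          # per-protein planted latents
    truth_meta: dict             # planted parameters (rates, strata, ...)


# ----------------------------------------------------------------------
# seed plumbing: one child stream per generated table, so regenerating
# e.g. only the intensities never perturbs the tree or the edges

_STAGES = ("latents", "intensities", "missing", "tree", "homology",
           "pathways", "edges", "mutations")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(child)
            for name, child in zip(_STAGES, children)}


def _cell_line_names(n: int) -> list[str]:
    if n == len(CELL_LINES):
        return list(CELL_LINES)
    return [f"CL{i + 1:02d}" for i in range(n)]


# ----------------------------------------------------------------------
# latent per-protein structure

def _simulate_latents(config: WorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_proteins
    ids = [f"P{i + 1:05d}" for i in range(n)]
    a = rng.normal(config.abundance_log_mean, config.abundance_log_sd, n)
    fr = dict(config.layer_fractions)
    layers = rng.choice(LAYERS, size=n, p=[fr[l] for l in LAYERS])
    mult = dict(config.layer_variability_multipliers)
    v = np.array([mult[l] for l in layers]) * np.exp(
        rng.normal(0.0, config.within_layer_variability_sd, n))
    sigma = config.replicate_noise_sd * np.power(
        10.0, -config.noise_abundance_exponent * (a - config.abundance_log_mean))
    tau = config.between_cell_scale * np.sqrt(v) * sigma
    # functional class consistent with the layer
    classes = np.empty(n, dtype=object)
    for i, l in enumerate(layers):
        if l == "input":
            classes[i] = "receptor"
        elif l == "output":
            classes[i] = "transcription_factor"
        elif l == "transmission":
            classes[i] = TRANSMISSION_CLASSES[rng.integers(len(TRANSMISSION_CLASSES))]
        else:
            classes[i] = "ligand" if rng.random() < 0.5 else "none"
    return pd.DataFrame(
        {"layer": layers, "log_abundance": a, "variability_factor": v,
         "noise_sd": sigma, "between_sd": tau, "raw_class": classes},
        index=pd.Index(ids, name="protein_id"),
    )


# ----------------------------------------------------------------------
# intensity matrix

def _simulate_intensities(config: WorldConfig, latents: pd.DataFrame,
                          rng_int: np.random.Generator,
                          rng_miss: np.random.Generator) -> IntensityMatrix:
    n = config.n_proteins
    lines = _cell_line_names(config.n_cell_lines)
    reps = config.n_replicates_per_line
    a = latents["log_abundance"].to_numpy()
    tau = latents["between_sd"].to_numpy()
    sigma = latents["noise_sd"].to_numpy()

    offsets = rng_int.normal(0.0, 1.0, (n, len(lines))) * tau[:, None]
    cols, data = [], []
    for j, line in enumerate(lines):
        for r in range(reps):
            cols.append(f"{line}.rep{r + 1}")
            noise = rng_int.normal(0.0, 1.0, n) * sigma
            data.append(a + offsets[:, j] + noise)
    log_vals = np.column_stack(data)

    if config.missing_fraction > 0:
        # detection-limit missingness: proteins below a latent-abundance
        # threshold drop out of most runs (and are removed by the 50%
        # detection filter), proteins above it are essentially complete.
        # The sharp logistic emulates a limit of detection; the threshold
        # is placed so the overall missing-cell rate matches the target.
        from scipy.stats import norm
        ceiling = 0.95
        t = config.abundance_log_mean + config.abundance_log_sd * norm.ppf(
            min(config.missing_fraction / ceiling, 0.999))
        p = ceiling * expit((t - a) / (0.1 * config.abundance_log_sd))
        mask = rng_miss.random((n, log_vals.shape[1])) < p[:, None]
        log_vals = np.where(mask, np.nan, log_vals)

    values = pd.DataFrame(np.power(10.0, log_vals),
                          index=latents.index, columns=cols)
    return IntensityMatrix(values)


def generate_intensities(config: WorldConfig) -> IntensityMatrix:
    """The intensity matrix alone (identical to the one inside
    :func:`generate_world` for the same config)."""
    streams = _streams(config.seed)
    latents = _simulate_latents(config, streams["latents"])
    return _simulate_intensities(config, latents, streams["intensities"],
                                 streams["missing"])


# ----------------------------------------------------------------------
# species tree + homology

def _random_tree_newick(rng: np.random.Generator, tips: list[str],
                        lo: float = 0.02, hi: float = 0.25) -> str:
    nodes = [f"{t}:{rng.uniform(lo, hi):.6f}" for t in tips]
    # tip branch lengths already attached; join random pairs until rooted binary
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(lo, hi):.6f}"
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


def _tip_distances_from(tree: cons.SpeciesTree, ref: str) -> pd.Series:
    h = tree.tip_labels.index(ref)
    dists = {}
    for t, label in enumerate(tree.tip_labels):
        on_path = tree.edge_masks[:, h] != tree.edge_masks[:, t]
        dists[label] = float(tree.edge_lengths[on_path].sum())
    return pd.Series(dists)


def _simulate_homology(config: WorldConfig, latents: pd.DataFrame,
                       tree: cons.SpeciesTree,
                       rng: np.random.Generator) -> dict[str, set[str]]:
    a = latents["log_abundance"].to_numpy()
    z = (a - config.abundance_log_mean) / config.abundance_log_sd
    offs = dict(config.layer_conservation_offsets)
    layer_off = np.array([offs.get(l, 0.0) for l in latents["layer"]])
    dists = _tip_distances_from(tree, cons.REFERENCE_SPECIES)
    species = [s for s in tree.tip_labels if s != cons.REFERENCE_SPECIES]
    d = dists[species].to_numpy()
    d_norm = d / d.mean()
    logits = (config.homology_base
              + config.conservation_abundance_effect * z[:, None]
              + layer_off[:, None]
              - config.homology_distance_scale * d_norm[None, :])
    keep = rng.random(logits.shape) < expit(logits)
    return {pid: {sp for sp, k in zip(species, row) if k}
            for pid, row in zip(latents.index, keep)}


# ----------------------------------------------------------------------
# pathway membership and functional classes

def _simulate_pathways(config: WorldConfig, latents: pd.DataFrame,
                       scores: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    labels = (DEFAULT_PATHWAY_LABELS[: config.n_pathways]
              if config.n_pathways <= len(DEFAULT_PATHWAY_LABELS)
              else [f"PW{i + 1:02d}" for i in range(config.n_pathways)])
    n = len(latents)
    z_cons = (scores - scores.mean()) / max(scores.std(), 1e-12)
    base = logit(np.clip(config.multi_pathway_fraction, 1e-6, 1 - 1e-6))
    p_multi = expit(base + config.multi_pathway_conservation_bias
                    * z_cons.to_numpy())
    rows = []
    for i, pid in enumerate(latents.index):
        raw_class = latents["raw_class"].iloc[i]
        source = "signalink" if raw_class in ("mediator", "cofactor", "ligand") \
            else "reactome"
        k = 1
        if rng.random() < p_multi[i]:
            k = 2 + int(rng.random() < 0.3)
        member = rng.choice(len(labels), size=min(k, len(labels)), replace=False)
        for m in member:
            rows.append((pid, labels[m], source, raw_class))
        # a small fraction carries a conflicting second class -> ambiguous
        if rng.random() < config.ambiguous_fraction:
            other = "transcription_factor" if raw_class != "transcription_factor" \
                else "kinase"
            rows.append((pid, labels[member[0]], "reactome", other))
    return pd.DataFrame(rows, columns=["protein_id", "pathway_id", "source",
                                       "raw_class"])


# ----------------------------------------------------------------------
# PPI edges

def _draw_edges(rng: np.random.Generator, side_a: np.ndarray, side_b: np.ndarray,
                target: int, existing: set, forbid=None) -> None:
    attempts = 0
    start = len(existing)
    while len(existing) - start < target and attempts < 50 * max(target, 1):
        a = side_a[rng.integers(side_a.size)]
        b = side_b[rng.integers(side_b.size)]
        attempts += 1
        if a == b or (forbid is not None and forbid(a, b)):
            continue
        existing.add((a, b) if a <= b else (b, a))


def _simulate_edges(config: WorldConfig, latents: pd.DataFrame,
                    rng: np.random.Generator) -> tuple[EdgeList, dict]:
    layers = latents["layer"]
    v = latents["variability_factor"]
    sig = latents.index[layers.isin(["input", "transmission", "output"])].to_numpy()
    inp = latents.index[layers == "input"].to_numpy()
    tra = latents.index[layers == "transmission"].to_numpy()
    outp = latents.index[layers == "output"].to_numpy()
    if min(inp.size, tra.size, outp.size) < 2:
        raise ConfigError("each signaling layer needs at least 2 proteins for edges")

    # order each layer by planted variability for rank-coupled draws
    in_sorted = inp[np.argsort(v[inp].to_numpy(), kind="mergesort")]
    tr_sorted = tra[np.argsort(v[tra].to_numpy(), kind="mergesort")]

    m_total = int(round(config.edges_per_protein * config.n_proteins))
    m_it = int(0.30 * m_total)
    m_to = int(0.15 * m_total)
    m_w = int(0.25 * m_total)

    edges: set = set()
    w = config.wiring_assortativity
    q = config.assortative_quantile
    # Assortative input-transmission wiring: with probability w an edge is
    # variability-DISCORDANT — it joins a top-q most-variable protein of
    # one layer to a bottom-q least-variable protein of the other, the
    # orientation chosen by a fair coin.  Every coupled pair is therefore
    # extreme-unlike in variability.  Permuting the transmission
    # endpoints among sampled pairs preserves the endpoint marginals but
    # recombines half of the coupled pairs into concordant extreme pairs
    # (top-top / bottom-bottom), whose |Δ log F| collapses to the
    # between-layer gap — the signal the Perm-IT control probes.
    n_in, n_tr = in_sorted.size, tr_sorted.size
    top_in = in_sorted[int(np.ceil((1 - q) * n_in)):]
    bot_in = in_sorted[: max(int(q * n_in), 1)]
    top_tr = tr_sorted[int(np.ceil((1 - q) * n_tr)):]
    bot_tr = tr_sorted[: max(int(q * n_tr), 1)]
    n_coupled = int(rng.binomial(m_it, w)) if m_it else 0
    attempts = 0
    while len(edges) < n_coupled and attempts < 50 * max(n_coupled, 1):
        if rng.random() < 0.5:
            a = top_in[rng.integers(top_in.size)]
            b = bot_tr[rng.integers(bot_tr.size)]
        else:
            a = bot_in[rng.integers(bot_in.size)]
            b = top_tr[rng.integers(top_tr.size)]
        attempts += 1
        edges.add((a, b) if a <= b else (b, a))
    _draw_edges(rng, inp, tra, m_it - len(edges), edges)
    _draw_edges(rng, tra, outp, m_to, edges)
    for layer_arr in (inp, tra, outp):
        _draw_edges(rng, layer_arr, layer_arr, m_w // 3, edges)
    # unstructured remainder; input-transmission combinations are excluded
    # so the IT edge population keeps exactly the configured coupled share
    lay = latents["layer"]
    is_it = lambda a, b: {lay[a], lay[b]} == {"input", "transmission"}  # noqa: E731
    _draw_edges(rng, sig, sig, m_total - len(edges), edges, forbid=is_it)
    meta = {"n_edges": len(edges), "n_it_target": m_it,
            "n_it_coupled": n_coupled}
    return EdgeList(sorted(edges)), meta


# ----------------------------------------------------------------------
# mutations

def _simulate_mutations(config: WorldConfig, scores: pd.Series,
                        rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    shapes = {k: np.asarray(v, dtype=float)
              for k, v in config.mutation_profile_shapes.items()}
    k = len(next(iter(shapes.values())))
    bins, _ = quantile_bin(scores, k)
    counts = {}
    for cls, rates in shapes.items():
        counts[f"n_{cls}"] = rng.poisson(rates[bins])
    df = pd.DataFrame(counts, index=scores.index)
    df.index.name = "protein_id"
    bin_df = pd.DataFrame({"conservation_bin": bins}, index=scores.index)
    return df, bin_df


# ----------------------------------------------------------------------

def generate_world(config: WorldConfig) -> World:
    """Generate the six mutually consistent tables plus ground truth."""
    streams = _streams(config.seed)
    latents = _simulate_latents(config, streams["latents"])
    intensities = _simulate_intensities(config, latents, streams["intensities"],
                                        streams["missing"])
    tips = [cons.REFERENCE_SPECIES] + NONHUMAN_SPECIES
    tree = cons.read_newick(_random_tree_newick(streams["tree"], tips))
    homology = _simulate_homology(config, latents, tree, streams["homology"])
    score_df = cons.conservation_scores(tree, homology)
    scores = score_df["score"]
    pathways = _simulate_pathways(config, latents, scores, streams["pathways"])
    edges, edge_meta = _simulate_edges(config, latents, streams["edges"])
    mutations, bin_df = _simulate_mutations(config, scores, streams["mutations"])

    truth = latents.join(scores.rename("conservation_score")).join(bin_df)
    truth_meta = {
        "config": config.as_dict(),
        "mutation_rates_per_bin": {k: list(map(float, v))
                                   for k, v in config.mutation_profile_shapes.items()},
        "edges": dict(edge_meta),
        "layer_sizes": truth["layer"].value_counts().to_dict(),
    }
    return World(config, intensities, homology, tree, pathways, edges,
                 mutations, truth, truth_meta)


def write_world(world: World, outdir) -> dict[str, Path]:
    """Write all six tables plus the ground-truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": outdir / "intensities.tsv",
        "homology": outdir / "homology.tsv",
        "tree": outdir / "species_tree.nwk",
        "pathways": outdir / "pathways.tsv",
        "edges": outdir / "ppi_edges.tsv",
        "mutations": outdir / "mutations.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    world.intensities.write_tsv(paths["intensities"])
    hom = pd.DataFrame(
        {"protein_id": list(world.homology.keys()),
         "species": [",".join(sorted(s)) for s in world.homology.values()]}
    )
    hom.to_csv(paths["homology"], sep="\t", index=False)
    world.tree.write_newick(paths["tree"])
    world.pathways.to_csv(paths["pathways"], sep="\t", index=False)
    world.edges.write_tsv(paths["edges"])
    world.mutations.to_csv(paths["mutations"], sep="\t")
    truth = {
        "meta": world.truth_meta,
        "per_protein": {
            "layer": world.truth["layer"].to_dict(),
            "conservation_bin": {k: int(v) for k, v in
                                 world.truth["conservation_bin"].items()},
        },
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
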