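"""Functional classes, bow-tie layers, and class/layer feature comparisons.

Signaling proteins are assigned a unique functional class from their
pathway annotations (receptor, kinase, phosphatase, adaptor, GTPase
binding, transcription factor, ligand, mediator, cofactor); proteins
matching two or more classes are ``ambiguous`` and excluded from layer
analyses.  Classes are then pooled into the bow-tie layers:

    input        <- receptors
    transmission <- kinases, phosphatases, adaptors, GTPase binding
                    proteins, mediators, cofactors
    output       <- transcription factors

Ligands and ambiguous/unclassified proteins stay ``unassigned``.
Because a mediator or cofactor that is also annotated as a receptor or
transcription factor is ambiguous by the uniqueness rule, only
mediators/cofactors that are neither receptors nor transcription
factors reach the transmission layer.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stats_core import ComparisonResult, rank_sum_test

__all__ = [
    "VALID_CLASSES",
    "LAYER_OF_CLASS",
    "assign_functional_class",
    "pool_layers",
    "annotate",
    "class_feature_test",
    "layer_feature_summary",
    "split_exclusive_multiple",
    "quantile_bin",
]

VALID_CLASSES = {
    "receptor",
    "kinase",
    "phosphatase",
    "adaptor",
    "gtpase_binding",
    "transcription_factor",
    "ligand",
    "mediator",
    "cofactor",
    "none",
}

LAYER_OF_CLASS = {
    "receptor": "input",
    "kinase": "transmission",
    "phosphatase": "transmission",
    "adaptor": "transmission",
    "gtpase_binding": "transmission",
    "mediator": "transmission",
    "cofactor": "transmission",
    "transcription_factor": "output",
    "ligand": "unassigned",
    "none": "unassigned",
    "ambiguous": "unassigned",
}

#: the ten consolidated top-level pathway labels shipped as defaults
DEFAULT_PATHWAY_LABELS = ["DR", "MO", "GE", "MT", "MB", "ST", "AP", "DB", "TM", "CO"]


def assign_functional_class(pathway_table: pd.DataFrame) -> pd.DataFrame:
    """Unique functional class per protein.

    ``pathway_table`` has columns (protein_id, pathway_id, source,
    raw_class); a protein may appear in several rows.  The class is the
    single distinct non-``none`` raw_class supported by its rows;
    proteins supported by >= 2 distinct classes become ``ambiguous``,
    proteins with no class ``none``.  Unknown raw_class values are an
    error.

    Returns a DataFrame indexed by protein_id with columns
    ``functional_class``, ``pathway_count``, ``exclusive``.
    """
    unknown = set(pathway_table["raw_class"].unique()) - VALID_CLASSES
    if unknown:
        raise ValueError(f"unknown raw_class value(s): {sorted(unknown)}")
    grouped = pathway_table.groupby("protein_id")

    def _resolve(classes: pd.Series) -> str:
        distinct = set(classes) - {"none"}
        if not distinct:
            return "none"
        if len(distinct) == 1:
            return distinct.pop()
        return "ambiguous"

    cls = grouped["raw_class"].apply(_resolve)
    n_pathways = grouped["pathway_id"].nunique()
    out = pd.DataFrame(
        {
            "functional_class": cls,
            "pathway_count": n_pathways,
            "exclusive": n_pathways == 1,
        }
    )
    out.index.name = "protein_id"
    return out


def pool_layers(classes: pd.DataFrame) -> pd.DataFrame:
    """Add the bow-tie ``layer`` column to a functional-class table."""
    out = classes.copy()
    out["layer"] = out["functional_class"].map(LAYER_OF_CLASS)
    return out


def annotate(pathway_table: pd.DataFrame) -> pd.DataFrame:
    """Convenience: class assignment followed by layer pooling."""
    return pool_layers(assign_functional_class(pathway_table))


def class_feature_test(
    feature: pd.Series,
    members: Iterable[str],
    universe: Iterable[str],
    alpha: float = 0.01,
) -> ComparisonResult:
    """Rank-sum test of a feature in a protein class vs its complement
    within ``universe``.  Proteins lacking a feature value are dropped
    per-test."""
    universe = pd.Index(set(universe))
    members = pd.Index(set(members)).intersection(universe)
    rest = universe.difference(members)
    a = feature.reindex(members).dropna()
    b = feature.reindex(rest).dropna()
    if a.empty or b.empty:
        raise ValueError("class_feature_test: empty member or complement side")
    return rank_sum_test(a, b, alpha=alpha)


_FEATURES = ["log10_f", "score", "mean_abundance"]


def layer_feature_summary(
    features: pd.DataFrame,
    layers: pd.DataFrame,
    feature_names: Iterable[str] = _FEATURES,
    alpha: float = 0.01,
) -> dict:
    """Per-layer medians/IQRs and pairwise rank-sum tests.

    ``features`` is indexed by protein_id and holds the feature columns
    (typically log10_f, conservation score, mean_abundance); ``layers``
    carries the ``layer`` column.  Layers with fewer than 2 proteins are
    excluded with a warning.  Returns a dict::

        {feature: {"per_layer": {layer: {n, median, iqr}},
                   "pairwise": {"input_vs_transmission": ComparisonResult, ...}}}
    """
    merged = features.join(layers["layer"], how="inner")
    merged = merged[merged["layer"].isin(["input", "transmission", "output"])]
    report: dict = {}
    for feat in feature_names:
        if feat not in merged.columns:
            continue
        groups = {}
        for layer, sub in merged.groupby("layer"):
            vals = sub[feat].dropna()
            if len(vals) < 2:
                warnings.warn(f"layer {layer!r} has <2 proteins with {feat}; excluded",
                              stacklevel=2)
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            groups[layer] = {"n": int(len(vals)), "median": float(med),
                             "iqr": float(q3 - q1), "values": vals}
        if len(groups) < 2:
            raise ValueError(f"fewer than 2 layers populated for feature {feat!r}")
        pairwise = {}
        order = [l for l in ("input", "transmission", "output") if l in groups]
        for i, la in enumerate(order):
            for lb in order[i + 1:]:
                pairwise[f"{la}_vs_{lb}"] = rank_sum_test(
                    groups[la]["values"], groups[lb]["values"], alpha=alpha)
        report[feat] = {
            "per_layer": {k: {kk: vv for kk, vv in v.items() if kk != "values"}
                          for k, v in groups.items()},
            "pairwise": pairwise,
        }
    return report


def split_exclusive_multiple(
    pathway_table: pd.DataFrame,
    features: pd.DataFrame,
    feature_names: Iterable[str] = _FEATURES,
    alpha: float = 0.01,
) -> dict:
    """Exclusive (single-pathway) vs multiple-pathway protein comparison.

    Partitions proteins by pathway_count == 1 vs > 1, compares each
    feature between the two sets, and reports per-class
    overrepresentation among multiple-pathway proteins as fold over
    random expectation (observed count / (class frequency x set size)).
    Comparisons are skipped when one side is empty.
    """
    ann = assign_functional_class(pathway_table)
    exclusive = set(ann.index[ann["pathway_count"] == 1])
    multiple = set(ann.index[ann["pathway_count"] > 1])
    comparisons: dict[str, ComparisonResult] = {}
    if exclusive and multiple:
        for feat in feature_names:
            if feat not in features.columns:
                continue
            a = features[feat].reindex(pd.Index(exclusive)).dropna()
            b = features[feat].reindex(pd.Index(multiple)).dropna()
            if a.empty or b.empty:
                continue
            comparisons[feat] = rank_sum_test(a, b, alpha=alpha)

    folds: dict[str, float] = {}
    classes = ann["functional_class"]
    n_total = len(ann)
    n_multi = len(multiple)
    if n_multi:
        for cls, n_cls in classes.value_counts().items():
            if cls in ("none", "ambiguous"):
                continue
            observed = int((classes.reindex(pd.Index(multiple)) == cls).sum())
            expected = n_cls / n_total * n_multi
            folds[cls] = observed / expected if expected > 0 else float("nan")
    return {
        "exclusive": exclusive,
        "multiple": multiple,
        "comparisons": comparisons,
        "fold_over_expectation": folds,
    }


def quantile_bin(values: pd.Series | np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rank-based bins of near-equal occupancy.

    Ties share the mid-rank of their group and are assigned as a block
    to the lower bin, so bin sizes differ from n/k by at most the size
    of a tie group.  Returns ``(bin_indices, edges)`` where
    ``bin_indices`` are in 0..k-1 (NaN values get -1) and ``edges`` are
    the k+1 value quantiles.

    Raises if fewer than ``k`` distinct finite values exist.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    vals = arr[finite]
    if np.unique(vals).size < k:
        raise ValueError(f"need at least {k} distinct values to form {k} bins")
    n = vals.size
    # minimum rank of each tie group -> whole group lands in the lower bin
    order = np.argsort(vals, kind="mergesort")
    ranks_min = np.empty(n, dtype=np.int64)
    sorted_vals = vals[order]
    group_start = np.concatenate([[0], np.flatnonzero(np.diff(sorted_vals)) + 1])
    starts = np.repeat(group_start, np.diff(np.concatenate([group_start, [n]])))
    ranks_min[order] = starts
    bins = np.minimum((ranks_min * k) // n, k - 1)
    edges = np.quantile(vals, np.linspace(0, 1, k + 1))
    out = np.full(arr.shape, -1, dtype=int)
    out[finite] = bins
    return out, edges
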