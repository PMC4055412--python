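"""Disease-mutation analyses: somatic vs germline carrier comparisons,
binned mutation-rate profiles, and hypergeometric term enrichment.

Per-protein counts of somatic missense mutations (cancer-derived),
germline disease mutations, and background SNPs are related to the
protein features (conservation, log F variability, mean abundance):

* carrier comparisons — proteins with >= 1 somatic mutation vs proteins
  with >= 1 germline mutation, rank-sum on a chosen feature;
* binned profiles — proteins are split into k rank-based feature bins
  and the mean number of mutations per protein in each bin is reported
  per class (optionally normalized by the class mean so classes share
  one axis);
* enrichment — one-sided hypergeometric over-representation of
  annotation terms in a protein set with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .pathway_layers import quantile_bin
from .stats_core import ComparisonResult, rank_sum_test

__all__ = [
    "MUTATION_CLASSES",
    "BinnedProfile",
    "read_mutations_tsv",
    "mutation_class_comparison",
    "binned_mutation_profile",
    "enrichment_test",
]

MUTATION_CLASSES = ("somatic", "germline", "snp")


@dataclass
class BinnedProfile:
    """Per-bin mean mutation counts for each mutation class.

    ``per_bin_mean[cls]`` is a length-k array of mean mutations per
    protein; ``bin_counts`` the number of proteins per bin.  The exact
    identity sum(bin_counts * per_bin_mean[cls]) == total count of
    class cls holds by construction.
    """

    feature: str
    k: int
    edges: np.ndarray
    bin_counts: np.ndarray
    per_bin_mean: dict[str, np.ndarray]
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "k": self.k,
            "edges": [float(e) for e in self.edges],
            "bin_counts": [int(c) for c in self.bin_counts],
            "per_bin_mean": {c: [float(v) for v in m]
                             for c, m in self.per_bin_mean.items()},
            "normalized": self.normalized,
        }


def read_mutations_tsv(path) -> pd.DataFrame:
    """Read the (protein_id, n_somatic, n_germline, n_snp) table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("n_somatic", "n_germline", "n_snp"):
        if col not in df.columns:
            raise ValueError(f"mutation table missing column {col!r}")
        if (df[col] < 0).any():
            raise ValueError(f"negative counts in {col}")
    return df


def mutation_class_comparison(
    features: pd.DataFrame,
    counts: pd.DataFrame,
    feature_name: str,
    alpha: float = 0.01,
) -> ComparisonResult:
    """Rank-sum test of ``feature_name`` between somatic-mutation
    carriers and germline-mutation carriers.

    A protein carrying both mutation types contributes to both groups.
    """
    merged = features.join(counts, how="inner")
    somatic = merged.loc[merged["n_somatic"] > 0, feature_name].dropna()
    germline = merged.loc[merged["n_germline"] > 0, feature_name].dropna()
    if somatic.empty or germline.empty:
        raise ValueError("empty somatic or germline carrier group")
    return rank_sum_test(somatic, germline, alpha=alpha)


def binned_mutation_profile(
    features: pd.DataFrame,
    counts: pd.DataFrame,
    feature_name: str,
    k: int = 5,
    normalize: bool = False,
) -> BinnedProfile:
    """Mean mutations per protein in k rank-based bins of a feature.

    Proteins with a missing feature value are excluded; proteins with
    zero mutations in a class still contribute zeros to that class's
    bin means.  With ``normalize`` each class profile is divided by the
    class's overall mean count, putting all classes on one relative
    axis.
    """
    merged = features[[feature_name]].join(counts, how="inner").dropna(
        subset=[feature_name])
    bins, edges = quantile_bin(merged[feature_name], k)
    merged = merged.assign(_bin=bins)
    merged = merged[merged["_bin"] >= 0]
    bin_counts = merged.groupby("_bin").size().reindex(range(k), fill_value=0).to_numpy()
    per_bin = {}
    for cls in MUTATION_CLASSES:
        col = f"n_{cls}"
        if col not in merged.columns:
            continue
        sums = merged.groupby("_bin")[col].sum().reindex(range(k), fill_value=0).to_numpy()
        with np.errstate(invalid="ignore"):
            mean = np.where(bin_counts > 0, sums / np.maximum(bin_counts, 1), np.nan)
        if normalize:
            overall = merged[col].mean()
            mean = mean / overall if overall > 0 else mean
        per_bin[cls] = mean
    return BinnedProfile(feature_name, k, edges, bin_counts, per_bin,
                         normalized=normalize)


def enrichment_test(
    target_set: Iterable[str],
    annotation_map: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of annotation terms
    in ``target_set`` against ``background``, Bonferroni-corrected by
    the number of tested terms.

    For a term annotating K of the N background proteins, with n target
    proteins of which x carry the term, the raw p-value is
    P[X >= x] for X ~ Hypergeometric(N, K, n).  Returns a DataFrame
    sorted by corrected p with columns ``term``, ``overlap``,
    ``term_size``, ``p_raw``, ``p_bonferroni``.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    target = set(target_set)
    if not target <= background:
        raise ValueError("target_set must be a subset of background")
    rows = []
    n = len(target)
    N = len(background)
    for term, members in annotation_map.items():
        members = set(members)
        if not members <= background:
            raise ValueError(f"annotation set {term!r} is not a subset of background")
        K = len(members)
        x = len(members & target)
        # P[X >= x] = survival function at x-1
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        rows.append((term, x, K, min(p, 1.0)))
    m = len(rows)
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p_raw"])
    df["p_bonferroni"] = np.minimum(df["p_raw"] * m, 1.0)
    return df.sort_values("p_bonferroni", kind="mergesort").reset_index(drop=True)
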