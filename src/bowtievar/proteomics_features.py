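"""Per-protein abundance and variability features from a replicate-level
multi-cell-line intensity matrix.

The processing chain mirrors standard label-free proteomics practice:

1. keep proteins detected in at least a fraction of the MS runs
   (default 50%),
2. optionally log10-transform, then standardize every sample column to
   mean 0 / sd 1 over its detected entries,
3. mean abundance = row mean of the standardized values,
4. variability = one-way ANOVA F: between-cell-line mean square divided
   by within-cell-line mean square on the standardized values, with
   actual (unbalanced) per-group counts.

Because mass-spectrometry noise is larger for lowly abundant proteins,
the raw standard deviation is confounded with abundance; the variance
*ratio* F cancels the shared noise scale and isolates biological
between-cell-line variability.  ``confound_check`` reports both
correlations as a diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stats_core import ComparisonResult, CorrelationResult, correlation, rank_sum_test

__all__ = [
    "IntensityMatrix",
    "filter_detected",
    "standardize_samples",
    "mean_abundance",
    "f_value",
    "compute_features",
    "confound_check",
    "compare_reference_sets",
    "mouse_quartile_sets",
]

logger = logging.getLogger(__name__)

#: F for proteins whose within-cell-line mean square is exactly zero
UNDEFINED_F = np.inf


@dataclass
class IntensityMatrix:
    """Protein x sample intensities; NaN marks a missing measurement.

    Sample (column) labels follow the ``<CELL_LINE>.<replicate>`` dialect,
    e.g. ``HeLa.rep1``; the cell line is everything before the final dot.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy(dtype=float) < 0).any():
                raise ValueError("negative intensities are not allowed")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_labels(self) -> pd.Index:
        return self.values.columns

    def cell_line_map(self) -> pd.Series:
        """sample label -> cell line (label up to the final '.')."""
        return pd.Series(
            [c.rsplit(".", 1)[0] for c in self.values.columns],
            index=self.values.columns,
        )

    def detected_fraction(self) -> pd.Series:
        return self.values.notna().mean(axis=1)

    @classmethod
    def read_tsv(cls, path) -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(float))

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.10g")


def filter_detected(matrix: IntensityMatrix, min_fraction: float = 0.5) -> IntensityMatrix:
    """Retain proteins detected in at least ``min_fraction`` of samples.

    The boundary is inclusive: a protein seen in exactly half the runs
    passes a 0.5 threshold.  Columns are unchanged.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    keep = matrix.detected_fraction() >= min_fraction
    if not keep.any():
        warnings.warn("filter_detected removed every protein", stacklevel=2)
    out = IntensityMatrix.__new__(IntensityMatrix)  # skip sign check: works on z-scores too
    out.values = matrix.values.loc[keep]
    return out


def standardize_samples(matrix: IntensityMatrix, log_transform: bool = True) -> IntensityMatrix:
    """Column-wise z-scoring over detected entries.

    With ``log_transform`` the intensities are log10-transformed first
    (intensities span decades and are roughly log-normal).  After the
    transform every sample has mean 0 and sd 1 over its non-missing
    entries; missing entries stay missing.
    """
    vals = matrix.values.astype(float)
    if log_transform:
        with np.errstate(divide="ignore"):
            vals = np.log10(vals)
        vals = vals.replace(-np.inf, np.nan)
    counts = vals.notna().sum(axis=0)
    bad = counts[counts < 2]
    if len(bad):
        raise ValueError(f"sample(s) with fewer than 2 detected proteins: {list(bad.index)}")
    sd = vals.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-spread sample(s): {list(zero.index)}")
    std = (vals - vals.mean(axis=0)) / sd
    out = IntensityMatrix.__new__(IntensityMatrix)  # z-scores may be negative
    out.values = std
    return out


def mean_abundance(std_matrix: IntensityMatrix) -> pd.Series:
    """Row-wise mean of the standardized values over detected entries.

    Proteins with no detected value are excluded with a warning.
    """
    vals = std_matrix.values
    empty = vals.isna().all(axis=1)
    if empty.any():
        warnings.warn(f"{int(empty.sum())} protein(s) with no detected value excluded",
                      stacklevel=2)
    return vals.loc[~empty].mean(axis=1).rename("mean_abundance")


def f_value(
    std_matrix: IntensityMatrix,
    cell_line_map: Mapping[str, str] | pd.Series | None = None,
    min_lines: int = 2,
    min_lines_with_replicates: int = 2,
) -> pd.DataFrame:
    """One-way ANOVA F per protein: between-cell-line mean square over
    within-cell-line mean square, on detected values only.

    Groups are the cell lines; replicate counts may be unbalanced after
    missing-value removal.  Proteins failing the precondition (fewer
    than ``min_lines`` lines detected, or fewer than
    ``min_lines_with_replicates`` lines with >= 2 detected replicates)
    get status ``insufficient_groups``; a zero within-cell mean square
    gives status ``undefined_msw_zero`` with an infinite sentinel F.

    Returns a DataFrame with columns ``f_value``, ``log10_f``,
    ``n_lines``, ``n_obs``, ``status``.
    """
    if cell_line_map is None:
        lines = std_matrix.cell_line_map()
    else:
        lines = pd.Series(dict(cell_line_map)).reindex(std_matrix.sample_labels)
    vals = std_matrix.values.to_numpy(dtype=float)
    obs = np.isfinite(vals)
    uniq_lines = pd.unique(lines.to_numpy())
    n_prot = vals.shape[0]

    grp_n = np.zeros((n_prot, len(uniq_lines)))
    grp_sum = np.zeros((n_prot, len(uniq_lines)))
    grp_ss = np.zeros((n_prot, len(uniq_lines)))
    for g, line in enumerate(uniq_lines):
        cols = (lines.to_numpy() == line)
        sub = vals[:, cols]
        m = obs[:, cols]
        grp_n[:, g] = m.sum(axis=1)
        grp_sum[:, g] = np.where(m, sub, 0.0).sum(axis=1)
        grp_ss[:, g] = np.where(m, sub, 0.0).__pow__(2).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        grp_mean = grp_sum / grp_n
    n_tot = grp_n.sum(axis=1)
    grand = grp_sum.sum(axis=1) / np.where(n_tot > 0, n_tot, np.nan)
    n_lines = (grp_n > 0).sum(axis=1)
    lines_with_reps = (grp_n >= 2).sum(axis=1)

    ssb = np.nansum(grp_n * (grp_mean - grand[:, None]) ** 2, axis=1)
    ssw = np.nansum(grp_ss - grp_n * grp_mean**2, axis=1)
    ssw = np.maximum(ssw, 0.0)  # guard tiny negative rounding
    df1 = n_lines - 1
    df2 = n_tot - n_lines

    ok = (n_lines >= min_lines) & (lines_with_reps >= min_lines_with_replicates) & (df2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        msb = ssb / df1
        msw = ssw / df2
        f = msb / msw

    status = np.where(ok, "ok", "insufficient_groups")
    zero_msw = ok & (msw == 0)
    status = np.where(zero_msw, "undefined_msw_zero", status)
    f = np.where(zero_msw, UNDEFINED_F, f)
    f = np.where(ok, f, np.nan)

    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("f_value: %d protein(s) excluded (insufficient groups)", n_dropped)

    with np.errstate(divide="ignore", invalid="ignore"):
        log10_f = np.where(np.isfinite(f) & (f > 0), np.log10(np.where(f > 0, f, np.nan)), np.nan)
    return pd.DataFrame(
        {
            "f_value": f,
            "log10_f": log10_f,
            "n_lines": n_lines.astype(int),
            "n_obs": n_tot.astype(int),
            "status": status,
        },
        index=std_matrix.protein_ids,
    )


def compute_features(
    matrix: IntensityMatrix,
    min_detect: float = 0.5,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Full feature chain: detection filter, standardization, mean
    abundance and F value.

    Returns the ProteinFeatureTable: ``mean_abundance``, ``f_value``,
    ``log10_f``, ``detected_fraction`` indexed by protein_id (only
    proteins passing the detection filter).
    """
    filtered = filter_detected(matrix, min_detect)
    std = standardize_samples(filtered, log_transform=log_transform)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean_ab = mean_abundance(std)
    fv = f_value(std)
    out = pd.DataFrame(
        {
            "mean_abundance": mean_ab,
            "f_value": fv["f_value"],
            "log10_f": fv["log10_f"],
            "detected_fraction": filtered.detected_fraction(),
        }
    )
    out.index.name = "protein_id"
    return out


def raw_protein_sd(matrix: IntensityMatrix, log_transform: bool = True) -> pd.Series:
    """Per-protein standard deviation of (log) intensities across all
    samples — the abundance-confounded variability estimate."""
    vals = matrix.values.astype(float)
    if log_transform:
        with np.errstate(divide="ignore"):
            vals = np.log10(vals).replace(-np.inf, np.nan)
    return vals.std(axis=1, ddof=1).rename("raw_sd")


def confound_check(
    features: pd.DataFrame,
    raw_sd: pd.Series,
    method: str = "spearman",
) -> dict[str, CorrelationResult]:
    """Diagnostic for the abundance/variability confound.

    Returns correlations of (raw sd vs mean abundance) and (log F vs
    mean abundance).  A useful variability statistic shows a strong
    association in the first and none in the second.
    """
    if len(features) < 50:
        raise ValueError("confound_check needs at least 50 proteins")
    common = features.index.intersection(raw_sd.index)
    feats = features.loc[common]
    logf = feats["log10_f"].to_numpy()
    mean_ab = feats["mean_abundance"].to_numpy()
    out = {"raw_sd_vs_abundance": correlation(raw_sd.loc[common].to_numpy(),
                                              mean_ab, method=method)}
    if np.nanstd(logf) == 0:
        out["log_f_vs_abundance"] = CorrelationResult(
            float("nan"), float("nan"), len(common), method, undefined=True)
    else:
        out["log_f_vs_abundance"] = correlation(logf, mean_ab, method=method)
    return out


def compare_reference_sets(
    f_values: pd.Series,
    set_a: Iterable[str],
    set_b: Iterable[str],
    alpha: float = 0.01,
) -> ComparisonResult:
    """Rank-sum comparison of log F between two protein sets (e.g.
    housekeeping vs the rest, or low- vs high-variability mouse
    orthologs).  Sets are intersected with the available F values."""
    f_values = f_values[np.isfinite(f_values) & (f_values > 0)]
    a = f_values.reindex(pd.Index(set(set_a))).dropna()
    b = f_values.reindex(pd.Index(set(set_b))).dropna()
    if a.empty or b.empty:
        raise ValueError("a reference set has empty intersection with the F values")
    return rank_sum_test(np.log10(a), np.log10(b), alpha=alpha)


def mouse_quartile_sets(
    tissue_matrix: IntensityMatrix,
    ortholog_map: Mapping[str, str],
    log_transform: bool = True,
) -> tuple[set[str], set[str]]:
    """Low- and high-variability ortholog sets from a replicate-free
    tissue atlas.

    Without replicates the inter/intra variance ratio cannot be formed,
    so the confound is minimized instead: keep proteins detected in all
    tissues with mean (log) abundance above the global mean, then take
    the lowest and highest standard-deviation quartiles and map them to
    the reference species through ``ortholog_map`` (unmapped dropped).
    """
    vals = tissue_matrix.values.astype(float)
    if log_transform:
        with np.errstate(divide="ignore"):
            vals = np.log10(vals).replace(-np.inf, np.nan)
    complete = vals.dropna(axis=0)
    means = complete.mean(axis=1)
    abundant = complete.loc[means > means.mean()]
    if abundant.empty:
        raise ValueError("no protein passes the abundance filter")
    sds = abundant.std(axis=1, ddof=1)
    q1, q3 = np.quantile(sds, [0.25, 0.75])
    low = sds.index[sds <= q1]
    high = sds.index[sds >= q3]
    if low.empty or high.empty:
        raise ValueError("empty standard-deviation quartile")
    low_mapped = {ortholog_map[p] for p in low if p in ortholog_map}
    high_mapped = {ortholog_map[p] for p in high if p in ortholog_map}
    return low_mapped, high_mapped
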