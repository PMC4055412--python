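"""Edge resampling between bow-tie layers and the |Δ log F| machinery.

To ask whether physical interactions between the variable input layer
and the stable transmission layer connect proteins of *unlike*
variability, we sample protein pairs in six categories:

    PPI-IT    interacting pairs, one input / one transmission protein
    PPI-TO    interacting pairs, one transmission / one output protein
    PPI-W     interacting pairs within a single layer
    PPI-Rand  random interacting pairs (within the annotated universe)
    Rand-IT   NON-interacting input-transmission pairs
    Perm-IT   PPI-IT pairs with the transmission endpoints permuted

For each sampled pair the absolute difference in log10 F is recorded;
category distributions are compared with the two-sided rank-sum test.
Rand-IT controls for the layer marginals alone; Perm-IT keeps both
endpoint marginals of the interacting sample but destroys the
within-pair coupling, isolating the wiring preference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import ComparisonResult, rank_sum_test

__all__ = [
    "EdgeList",
    "PairSample",
    "sample_pairs",
    "abs_variability_diff",
    "permute_links",
    "compare_pair_distributions",
    "CATEGORIES",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("PPI-IT", "PPI-TO", "PPI-W", "PPI-Rand", "Rand-IT", "Perm-IT")

#: rejection-sampling attempt cap for Rand-IT, as a multiple of n
REJECTION_CAP = 10


class EdgeList:
    """Undirected, deduplicated protein-protein interaction edges."""

    def __init__(self, pairs: pd.DataFrame | list[tuple[str, str]]):
        if isinstance(pairs, pd.DataFrame):
            it = pairs.iloc[:, :2].itertuples(index=False, name=None)
        else:
            it = pairs
        edges = set()
        for a, b in it:
            if a == b:
                raise ValueError(f"self-loop on {a!r} rejected")
            edges.add((a, b) if a <= b else (b, a))
        self._edges = sorted(edges)
        self._edge_set = edges

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in self._edge_set

    def __iter__(self):
        return iter(self._edges)

    @classmethod
    def read_tsv(cls, path) -> "EdgeList":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(df)

    def write_tsv(self, path) -> None:
        pd.DataFrame(self._edges, columns=["protein_a", "protein_b"]).to_csv(
            path, sep="\t", index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._edges, columns=["protein_a", "protein_b"])


@dataclass
class PairSample:
    """A sample of protein pairs with their per-protein log10 F."""

    category: str
    pairs: list[tuple[str, str]]
    log_f: pd.Series
    seed: int
    with_replacement: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.pairs)


def _layer_sets(layers: pd.Series, log_f: pd.Series) -> dict[str, np.ndarray]:
    """Proteins per layer, restricted to those with a finite log F and a
    single layer assignment."""
    usable = log_f[np.isfinite(log_f)].index
    out = {}
    for layer in ("input", "transmission", "output"):
        out[layer] = np.array(sorted(set(layers.index[layers == layer]) & set(usable)))
    out["universe"] = np.concatenate([out["input"], out["transmission"], out["output"]])
    return out


def _eligible_edges(edges: EdgeList, sets: dict, category: str) -> list[tuple[str, str]]:
    inp, tra, outp = map(set, (sets["input"], sets["transmission"], sets["output"]))
    uni = inp | tra | outp
    elig = []
    for a, b in edges:
        if category == "PPI-IT":
            ok = (a in inp and b in tra) or (a in tra and b in inp)
        elif category == "PPI-TO":
            ok = (a in tra and b in outp) or (a in outp and b in tra)
        elif category == "PPI-W":
            ok = any(a in s and b in s for s in (inp, tra, outp))
        elif category == "PPI-Rand":
            ok = a in uni and b in uni
        else:
            raise ValueError(f"unknown PPI category {category!r}")
        if ok:
            elig.append((a, b))
    return elig


def sample_pairs(
    edges: EdgeList,
    layers: pd.Series,
    log_f: pd.Series,
    category: str,
    n: int = 1000,
    seed: int = 0,
) -> PairSample:
    """Sample ``n`` pairs of the given category.

    PPI categories draw uniformly from the eligible edges — without
    replacement when at least ``n`` exist, with replacement (logged)
    otherwise.  Rand-IT rejection-samples input-transmission pairs
    against the edge set, with an attempt cap of 10n.  Only proteins
    with a finite log F and a unique layer are eligible.
    """
    rng = np.random.default_rng(seed)
    sets = _layer_sets(layers, log_f)
    replace = False
    if category in ("PPI-IT", "PPI-TO", "PPI-W", "PPI-Rand"):
        elig = _eligible_edges(edges, sets, category)
        if not elig:
            raise ValueError(f"no eligible pairs for category {category}")
        replace = len(elig) < n
        if replace:
            logger.info("sample_pairs(%s): %d eligible < n=%d, sampling with replacement",
                        category, len(elig), n)
        idx = rng.choice(len(elig), size=n, replace=replace)
        pairs = [elig[i] for i in idx]
    elif category == "Rand-IT":
        if sets["input"].size == 0 or sets["transmission"].size == 0:
            raise ValueError("no eligible pairs for category Rand-IT")
        pairs = []
        attempts = 0
        cap = REJECTION_CAP * n
        while len(pairs) < n:
            if attempts >= cap:
                raise ValueError("Rand-IT rejection sampling exceeded attempt cap")
            a = sets["input"][rng.integers(sets["input"].size)]
            b = sets["transmission"][rng.integers(sets["transmission"].size)]
            attempts += 1
            if (a, b) in edges:
                continue
            pairs.append((a, b))
    else:
        raise ValueError(f"unknown category {category!r} (Perm-IT comes from permute_links)")
    return PairSample(category, pairs, log_f, seed, with_replacement=replace)


def abs_variability_diff(sample: PairSample) -> np.ndarray:
    """|Δ log10 F| per sampled pair."""
    lf = sample.log_f
    out = np.empty(sample.n)
    for i, (a, b) in enumerate(sample.pairs):
        out[i] = abs(lf[a] - lf[b])
    return out


def permute_links(sample: PairSample, seed: int = 0) -> PairSample:
    """Permutation control: keep the input-side endpoints in order and
    shuffle the transmission-side endpoints among the pairs.

    Both endpoint multisets are preserved exactly; the resulting pairs
    need not be interactions.  Requires a PPI-IT sample with n >= 2.
    """
    if sample.category != "PPI-IT":
        raise ValueError("permute_links expects a PPI-IT sample")
    if sample.n < 2:
        raise ValueError("permute_links requires at least 2 pairs")
    rng = np.random.default_rng(seed)
    # orient every pair as (input, transmission); sides were validated at sampling
    inputs = [p[0] for p in sample.pairs]
    trans = [p[1] for p in sample.pairs]
    perm = rng.permutation(sample.n)
    new_pairs = [(inputs[i], trans[perm[i]]) for i in range(sample.n)]
    return PairSample("Perm-IT", new_pairs, sample.log_f, seed,
                      meta={"permuted_from_seed": sample.seed})


def compare_pair_distributions(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    alpha: float = 0.01,
) -> ComparisonResult:
    """Two-sided rank-sum comparison of two |Δ log F| distributions."""
    return rank_sum_test(dist_a, dist_b, alpha=alpha)


def oriented_it_sample(
    edges: EdgeList,
    layers: pd.Series,
    log_f: pd.Series,
    n: int = 1000,
    seed: int = 0,
) -> PairSample:
    """PPI-IT sample with every pair oriented (input, transmission) —
    the orientation permute_links relies on."""
    sample = sample_pairs(edges, layers, log_f, "PPI-IT", n=n, seed=seed)
    input_set = set(layers.index[layers == "input"])
    sample.pairs = [(a, b) if a in input_set else (b, a) for a, b in sample.pairs]
    return sample
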