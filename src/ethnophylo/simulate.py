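"""Synthetic trees and communities with known clumping, plus calibration runs.

The generator produces ultrametric pure-birth (Yule) trees and presence
communities whose degree of phylogenetic clumping is controlled by a single
fraction f: ceil(f*n) of the n sampled tips are drawn from one focal clade,
the rest from outside it. f=0 is a uniform draw from all tips (the null the
signal tests assume); f=1 restricts the whole sample to the focal clade.
Because the downstream tests are invariant to branch-length rescaling, only
relative branch lengths matter and the pure-birth model (no extinction) is
sufficient; the birth rate defaults to 1, setting the time unit.

``calibration_experiment`` wires the generator to the signal tests to
measure type-I error (f=0: rejection rate should sit at alpha) and power
(f>0) over replicate (tree, community) pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import beta

from ._util import count_le, substream
from .phylo import Phylogeny
from .signal import NullModelConfig, _draw_indices, _METRIC_FUNCS, _observed

__all__ = [
    "SyntheticConfig",
    "simulate_yule_tree",
    "simulate_community",
    "calibration_experiment",
]


class SimulationError(ValueError):
    """Raised when a requested community structure is infeasible."""


@dataclass
class SyntheticConfig:
    """Study conditions for a calibration run.

    Defaults match the calibration design used throughout this package:
    100-tip Yule trees, samples of 10 tips, 500 replicate (tree, community)
    pairs. ``clump_fraction`` is the f described above.
    """

    n_tips: int = 100
    birth_rate: float = 1.0
    n_sample: int = 10
    clump_fraction: float = 0.0
    n_trees: int = 500
    communities_per_tree: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if not 2 <= self.n_sample <= self.n_tips:
            raise ValueError("need 2 <= n_sample <= n_tips")
        if not 0 <= self.clump_fraction <= 1:
            raise ValueError("clump_fraction must lie in [0, 1]")
        if self.n_trees < 0 or self.communities_per_tree < 0:
            raise ValueError("replicate counts must be nonnegative")


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Phylogeny:
    """Ultrametric pure-birth tree with ``n_tips`` tips labeled t1..tN.

    Grown forward in time: with k extant lineages the waiting time to the
    next split is Exponential(k * birth_rate) and the splitting lineage is
    chosen uniformly; growth stops on reaching ``n_tips`` and a final
    waiting time is added so every pendant edge has positive length. The
    construction is ultrametric by design and bit-reproducible for a fixed
    seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child(edge_length=0.0)
        active.append(child)
    while len(active) < n_tips:
        k = len(active)
        wait = rng.exponential(1.0 / (k * birth_rate))
        for leaf in active:
            leaf.edge.length += wait
        pick = int(rng.integers(k))
        parent = active.pop(pick)
        for _ in range(2):
            child = parent.new_child(edge_length=0.0)
            active.append(child)
    wait = rng.exponential(1.0 / (n_tips * birth_rate))
    for leaf in active:
        leaf.edge.length += wait
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"t{i}")
    return Phylogeny(tree)


def simulate_community(
    tree: Phylogeny,
    n_sample: int,
    clump_fraction: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Draw a presence community of ``n_sample`` tips with clumping f.

    m = ceil(f * n) tips come from one focal clade chosen uniformly among
    internal nodes whose descendant count D satisfies
    m <= D <= N - (n - m) (so both the clade and its complement can supply
    their shares); the remaining n - m tips are drawn uniformly outside the
    clade. Returns ``(tip set, focal node)``; for f=0 the draw is uniform
    over all tips and the focal node is None.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    N = tree.n_tips
    if not 1 <= n_sample <= N:
        raise SimulationError(f"need 1 <= n_sample <= {N}")
    if not 0 <= clump_fraction <= 1:
        raise SimulationError("clump_fraction must lie in [0, 1]")
    labels = tree.tip_labels
    m = math.ceil(clump_fraction * n_sample)
    if m == 0:
        chosen = rng.choice(N, size=n_sample, replace=False)
        return frozenset(labels[i] for i in chosen), None
    eligible = []
    for nd in tree.internal_nodes():
        tips = tree.descendant_tips(nd)
        if m <= len(tips) <= N - (n_sample - m):
            eligible.append((nd, tips))
    if not eligible:
        raise SimulationError(
            f"no internal node can host {m} of {n_sample} sampled tips "
            f"on this {N}-tip tree"
        )
    focal, clade_tips = eligible[int(rng.integers(len(eligible)))]
    inside = sorted(clade_tips)
    outside = sorted(set(labels) - clade_tips)
    sample = {inside[i] for i in rng.choice(len(inside), size=m, replace=False)}
    rest = n_sample - m
    if rest:
        sample |= {
            outside[i] for i in rng.choice(len(outside), size=rest, replace=False)
        }
    return frozenset(sample), focal


def _clopper_pearson(k: int, n: int, conf: float = 0.99) -> tuple[float, float]:
    a = (1 - conf) / 2
    lo = 0.0 if k == 0 else float(beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - a, k + 1, n - k))
    return lo, hi


def calibration_experiment(
    cfg: SyntheticConfig, null_cfg: Optional[NullModelConfig] = None
) -> pd.DataFrame:
    """Rejection rates of the signal tests over replicate synthetic data.

    Each replicate simulates a fresh Yule tree and community, runs the
    MPD and MNTD clumping tests against ``null_cfg``, and records whether
    p <= alpha. Returns one row per metric with the rejection rate and its
    Clopper-Pearson 99% interval; an empty config yields an empty report.
    Fully reproducible: every replicate derives its RNG from (seed, indices).
    """
    null_cfg = null_cfg or NullModelConfig()
    reps = cfg.n_trees * cfg.communities_per_tree
    if reps == 0:
        return pd.DataFrame(
            columns=[
                "clump_fraction", "metric", "alpha", "replicates",
                "rejections", "rate", "ci99_low", "ci99_high",
            ]
        )
    rejections = {m: 0 for m in _METRIC_FUNCS}
    for t in range(cfg.n_trees):
        tree = simulate_yule_tree(
            cfg.n_tips,
            cfg.birth_rate,
            rng=substream(cfg.seed, "tree", t),
        )
        dmat = tree.patristic_matrix()
        D = dmat.to_numpy()
        index = {l: i for i, l in enumerate(dmat.index)}
        for c in range(cfg.communities_per_tree):
            sample, _ = simulate_community(
                tree,
                cfg.n_sample,
                cfg.clump_fraction,
                rng=substream(cfg.seed, "community", t, c),
            )
            idx = np.asarray(sorted(index[s] for s in sample), dtype=np.intp)
            rng = substream(cfg.seed, "null", t, c)
            null = {m: np.empty(null_cfg.runs) for m in _METRIC_FUNCS}
            chunk = 4000
            for start in range(0, null_cfg.runs, chunk):
                runs = min(chunk, null_cfg.runs - start)
                draws = _draw_indices(
                    rng, runs, cfg.n_sample, cfg.n_tips, null_cfg.model
                )
                for m, fn in _METRIC_FUNCS.items():
                    null[m][start : start + runs] = fn(D, draws)
            for m in _METRIC_FUNCS:
                obs = _observed(m, D, idx)
                p = (count_le(null[m], obs) + 1) / (null_cfg.runs + 1)
                if p <= null_cfg.alpha:
                    rejections[m] += 1
    rows = []
    for m in ("mpd", "mntd"):
        k = rejections[m]
        lo, hi = _clopper_pearson(k, reps)
        rows.append(
            {
                "clump_fraction": cfg.clump_fraction,
                "metric": m,
                "alpha": null_cfg.alpha,
                "replicates": reps,
                "rejections": k,
                "rate": k / reps,
                "ci99_low": lo,
                "ci99_high": hi,
            }
        )
    return pd.DataFrame(rows)
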