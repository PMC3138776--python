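"""Phylogenetic-signal tests for use-category communities (comstruct-style).

For each sample (the set of taxa sharing a use) the observed mean pairwise
patristic distance (MPD) and mean nearest-taxon distance (MNTD) are compared
to a null distribution obtained by drawing equally sized random samples from
the full tip pool. Small distances mean phylogenetic clumping; the reported
p-value is one-tailed toward clumping:

    p = (k + 1) / (R + 1),  k = #{null values <= observed}

with ties counted conservatively as "more clumped or equal". Standardized
effect sizes follow the NRI/NTI sign convention,

    SES = (mean_null - observed) / sd_null,

so positive values indicate clumping. All statistics are invariant under
rescaling every branch length by a positive constant.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._util import count_le, substream
from .phylo import Phylogeny, normalize_label

__all__ = [
    "NullModelConfig",
    "mpd",
    "mntd",
    "null_distribution",
    "signal_test",
    "exact_signal_p",
    "MetricUndefinedError",
]

_CHUNK = 4000  # null draws evaluated per vectorized block


class MetricUndefinedError(ValueError):
    """Raised when a distance metric is requested for fewer than 2 taxa."""


@dataclass
class NullModelConfig:
    """Randomization settings shared by the signal and node tests.

    ``runs`` follows the community-phylogenetics convention of R = 999.
    ``model`` chooses between drawing n tips uniformly from the pool
    (``pool_draw``, the default — for presence data this matches shuffling
    tip labels) and an explicit tip-label permutation (``label_shuffle``).
    """

    runs: int = 999
    seed: int = 0
    model: str = "pool_draw"
    alpha: float = 0.05

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.model not in ("pool_draw", "label_shuffle"):
            raise ValueError(f"unknown null model {self.model!r}")


def _sample_indices(sample: Iterable[str], dmat: pd.DataFrame) -> np.ndarray:
    labels = [normalize_label(t) for t in sample]
    index = {l: i for i, l in enumerate(dmat.index)}
    unknown = sorted(set(l for l in labels if l not in index))
    if unknown:
        raise ValueError(
            "sample taxa not present in distance matrix: " + ", ".join(unknown)
        )
    idx = sorted({index[l] for l in labels})
    return np.asarray(idx, dtype=np.intp)


def _mpd_values(D: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """MPD for each row of a (runs, n) index array."""
    n = idx.shape[1]
    sub = D[idx[:, :, None], idx[:, None, :]]
    return sub.sum(axis=(1, 2)) / (n * (n - 1))


def _mntd_values(D: np.ndarray, idx: np.ndarray) -> np.ndarray:
    n = idx.shape[1]
    sub = D[idx[:, :, None], idx[:, None, :]].copy()
    rng = np.arange(n)
    sub[:, rng, rng] = np.inf
    return sub.min(axis=2).mean(axis=1)


_METRIC_FUNCS = {"mpd": _mpd_values, "mntd": _mntd_values}


def _observed(metric: str, D: np.ndarray, idx: np.ndarray) -> float:
    return float(_METRIC_FUNCS[metric](D, idx[None, :])[0])


def mpd(sample: Iterable[str], dmat: pd.DataFrame) -> float:
    """Mean patristic distance over all pairs in the sample (n >= 2)."""
    idx = _sample_indices(sample, dmat)
    if idx.size < 2:
        raise MetricUndefinedError("MPD is undefined for fewer than 2 taxa")
    return _observed("mpd", dmat.to_numpy(), idx)


def mntd(sample: Iterable[str], dmat: pd.DataFrame) -> float:
    """Mean distance from each sample taxon to its nearest co-sample taxon."""
    idx = _sample_indices(sample, dmat)
    if idx.size < 2:
        raise MetricUndefinedError("MNTD is undefined for fewer than 2 taxa")
    return _observed("mntd", dmat.to_numpy(), idx)


def _draw_indices(
    rng: np.random.Generator, runs: int, n: int, pool: int, model: str
) -> np.ndarray:
    """(runs, n) arrays of distinct tip indices under the chosen null."""
    order = np.argsort(rng.random((runs, pool)), axis=1)
    if model == "label_shuffle":
        # image of the first n positions under a full label permutation ==
        # uniform n-subset; kept as a distinct code path for clarity
        return order[:, :n]
    return order[:, :n]


def null_distribution(
    metric: str,
    n: int,
    dmat: pd.DataFrame,
    cfg: NullModelConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """R null metric values for random n-tip samples from the full pool."""
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}")
    N = dmat.shape[0]
    if not 2 <= n <= N:
        raise ValueError(f"need 2 <= n <= pool size ({n=}, pool={N})")
    rng = rng if rng is not None else substream(cfg.seed, "null", metric, n)
    D = dmat.to_numpy()
    out = np.empty(cfg.runs)
    fn = _METRIC_FUNCS[metric]
    for start in range(0, cfg.runs, _CHUNK):
        stop = min(start + _CHUNK, cfg.runs)
        idx = _draw_indices(rng, stop - start, n, N, cfg.model)
        out[start:stop] = fn(D, idx)
    return out


def _one_sample(
    name: str, idx: np.ndarray, D: np.ndarray, cfg: NullModelConfig
) -> dict:
    n = idx.size
    rng = substream(cfg.seed, "signal", name)
    row: dict = {"sample": name, "n": n}
    # one shared set of null draws feeds both metrics, as in Phylocom
    null = {m: np.empty(cfg.runs) for m in _METRIC_FUNCS}
    for start in range(0, cfg.runs, _CHUNK):
        stop = min(start + _CHUNK, cfg.runs)
        draws = _draw_indices(rng, stop - start, n, D.shape[0], cfg.model)
        for m, fn in _METRIC_FUNCS.items():
            null[m][start:stop] = fn(D, draws)
    for m in ("mpd", "mntd"):
        obs = _observed(m, D, idx)
        vals = null[m]
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if cfg.runs > 1 else 0.0
        ses = (mean - obs) / sd if sd > 0 else 0.0
        p = (count_le(vals, obs) + 1) / (cfg.runs + 1)
        row.update(
            {
                f"{m}_obs": obs,
                f"{m}_null_mean": mean,
                f"{m}_null_sd": sd,
                f"ses_{m}": ses,
                f"p_{m}": p,
            }
        )
    return row


def signal_test(
    matrix: pd.DataFrame,
    tree_or_dmat: Union[Phylogeny, pd.DataFrame],
    cfg: Optional[NullModelConfig] = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Clumping significance of every sample in a community matrix.

    ``matrix`` is samples x taxa presence (0/1); the tip pool is every tip
    of the tree (or row of the supplied distance matrix). Samples with fewer
    than 2 members are skipped with a warning. Returns one row per tested
    sample with observed metrics, null moments, SES and one-tailed p-values;
    ``bh_correction`` appends Benjamini-Hochberg adjusted columns (the
    default reports raw p only).
    """
    cfg = cfg or NullModelConfig()
    dmat = (
        tree_or_dmat.patristic_matrix()
        if isinstance(tree_or_dmat, Phylogeny)
        else tree_or_dmat
    )
    D = dmat.to_numpy()
    rows = []
    skipped = []
    for name in matrix.index:
        members = matrix.columns[matrix.loc[name].to_numpy() == 1]
        try:
            idx = _sample_indices(members, dmat)
        except ValueError:
            raise
        if idx.size < 2:
            skipped.append(name)
            continue
        rows.append(_one_sample(str(name), idx, D, cfg))
    if skipped:
        warnings.warn(
            "samples with fewer than 2 taxa skipped: "
            + ", ".join(map(str, skipped)),
            stacklevel=2,
        )
    if not rows:
        raise ValueError("no sample with >= 2 taxa to test")
    out = pd.DataFrame(rows).set_index("sample")
    if bh_correction:
        for m in ("mpd", "mntd"):
            out[f"p_{m}_bh"] = _bh_adjust(out[f"p_{m}"].to_numpy())
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def exact_signal_p(
    sample: Iterable[str],
    dmat: pd.DataFrame,
    metric: str = "mpd",
    cap: int = 10**6,
) -> float:
    """Exact one-tailed clumping p by full enumeration of n-subsets.

    p = #{subsets with metric <= observed} / C(N, n), ties counted as <=.
    Feasible only while C(N, n) stays below ``cap``; larger problems should
    use the permutation estimate.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}")
    idx = _sample_indices(sample, dmat)
    n, N = idx.size, dmat.shape[0]
    if n < 2:
        raise MetricUndefinedError("metric undefined for fewer than 2 taxa")
    total = math.comb(N, n)
    if total > cap:
        raise ValueError(
            f"C({N},{n}) = {total} exceeds enumeration cap {cap}; "
            "use the permutation test instead"
        )
    D = dmat.to_numpy()
    obs = _observed(metric, D, idx)
    fn = _METRIC_FUNCS[metric]
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(N), n)),
        dtype=np.intp,
    ).reshape(total, n)
    count = 0
    for start in range(0, total, _CHUNK):
        vals = fn(D, combos[start : start + _CHUNK])
        count += count_le(vals, obs)
    return count / total
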