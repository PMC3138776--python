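"""Per-node enrichment of use communities (nodesig-style "hot node" search).

Each internal node v of the phylogeny (root excluded — it trivially contains
every sample) is tested for overabundance of sample members among its D_v
descendant tips. Under the pool-draw null of n tips taken uniformly without
replacement from the N-tip pool, the member count X_v is exactly
Hypergeometric(N, D_v, n); the test is available both as that closed-form
tail (EXACT mode) and as the randomization estimate Phylocom uses
(PERMUTATION mode). A node is flagged MORE when the observed count beats the
null in at least 97.5% of runs (equivalently p_more <= 0.025 in EXACT mode);
underabundance (LESS) is computed and reported but not highlighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._util import substream
from .phylo import Phylogeny, normalize_label
from .signal import NullModelConfig

__all__ = [
    "node_counts",
    "hypergeom_node_p",
    "nodesig_test",
    "annotate_tree",
    "NodeEnrichment",
]

_CHUNK = 4000


def node_counts(tree: Phylogeny, sample: Iterable[str]) -> dict:
    """Sample-member count X_v below every node, in one post-order pass.

    Returns a mapping node -> count covering tips and internal nodes; for a
    tip the count is its own membership (0/1).
    """
    members = {normalize_label(t) for t in sample}
    unknown = sorted(m for m in members if not tree.has_tip(m))
    if unknown:
        raise ValueError("sample taxa not in tree: " + ", ".join(unknown))
    counts: dict = {}
    for nd in tree._tree.postorder_node_iter():
        if nd.is_leaf():
            counts[nd] = int(normalize_label(nd.taxon.label) in members)
        else:
            counts[nd] = sum(counts[ch] for ch in nd.child_nodes())
    return counts


def hypergeom_node_p(N: int, D: int, n: int, x: int) -> float:
    """Upper-tail P(X >= x) for X ~ Hypergeometric(N, D, n).

    N = tip pool size, D = descendant tips of the node, n = sample size,
    x = observed sample members below the node.
    """
    if not (0 <= D <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent arguments: {N=}, {D=}, {n=}")
    if not 0 <= x <= min(D, n):
        raise ValueError(f"observed count {x} outside [0, min(D, n)]")
    return float(hypergeom.sf(x - 1, N, D, n))


@dataclass
class NodeEnrichment:
    """Result of :func:`nodesig_test`: the tidy table plus flagged nodes."""

    table: pd.DataFrame
    flagged: dict[str, list[str]] = field(default_factory=dict)
    #: report-label -> tree node, for annotation
    nodes: dict[str, object] = field(default_factory=dict)


def _tested_nodes(tree: Phylogeny):
    """Internal nodes with 2 <= D_v <= N-1 (root and trivial clades excluded)."""
    N = tree.n_tips
    out = []
    for nd in tree.internal_nodes(exclude_root=True):
        tips = tree.descendant_tips(nd)
        if 2 <= len(tips) <= N - 1:
            out.append((nd, tips))
    return out


def nodesig_test(
    matrix: pd.DataFrame,
    tree: Phylogeny,
    cfg: Optional[NullModelConfig] = None,
    mode: str = "permutation",
    flag_fraction: float = 0.975,
    report_less: bool = True,
    bh_correction: bool = False,
) -> NodeEnrichment:
    """Test every eligible internal node for each sample of the matrix.

    PERMUTATION mode draws R random n-tip samples and estimates
    ``p_more = (#{null X >= x} + 1) / (R + 1)`` per node; a node is flagged
    MORE when the observed count strictly exceeds the null count in at least
    ``flag_fraction`` of runs (Phylocom's >= 975/1000 convention). EXACT
    mode uses the hypergeometric tail and flags at
    ``p_more <= 1 - flag_fraction``. Empty samples are skipped with a
    warning. ``bh_correction`` appends a per-sample Benjamini-Hochberg
    column (off by default — raw p matches the original reports).
    """
    cfg = cfg or NullModelConfig()
    if mode not in ("permutation", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    nodes = _tested_nodes(tree)
    tip_index = {l: i for i, l in enumerate(tree.tip_labels)}
    N = tree.n_tips
    A = np.zeros((len(nodes), N), dtype=np.uint8)  # node x tip membership
    labels = []
    node_map: dict[str, object] = {}
    for v, (nd, tips) in enumerate(nodes):
        for t in tips:
            A[v, tip_index[t]] = 1
        lab = tree.node_report_label(nd)
        labels.append(lab)
        node_map[lab] = nd
    D_v = A.sum(axis=1).astype(int)

    rows = []
    flagged: dict[str, list[str]] = {}
    skipped = []
    for name in matrix.index:
        members = [
            normalize_label(t)
            for t in matrix.columns[matrix.loc[name].to_numpy() == 1]
        ]
        if not members:
            skipped.append(name)
            continue
        unknown = sorted(set(m for m in members if m not in tip_index))
        if unknown:
            raise ValueError(
                f"sample {name!r} has taxa not in tree: " + ", ".join(unknown)
            )
        midx = np.asarray(sorted(tip_index[m] for m in set(members)), dtype=np.intp)
        n = midx.size
        x_obs = A[:, midx].sum(axis=1).astype(int)
        if mode == "exact":
            null_mean = n * D_v / N
            p_more = hypergeom.sf(x_obs - 1, N, D_v, n)
            p_less = hypergeom.cdf(x_obs, N, D_v, n)
            is_more = p_more <= (1.0 - flag_fraction)
            is_less = p_less <= (1.0 - flag_fraction)
        else:
            rng = substream(cfg.seed, "nodesig", str(name))
            ge = np.zeros(len(nodes), dtype=np.int64)  # null >= obs
            gt_obs = np.zeros(len(nodes), dtype=np.int64)  # obs > null
            lt_obs = np.zeros(len(nodes), dtype=np.int64)  # obs < null
            total = np.zeros(len(nodes), dtype=np.float64)
            for start in range(0, cfg.runs, _CHUNK):
                runs = min(_CHUNK, cfg.runs - start)
                order = np.argsort(rng.random((runs, N)), axis=1)[:, :n]
                S = np.zeros((runs, N), dtype=np.uint8)
                S[np.arange(runs)[:, None], order] = 1
                null_x = S @ A.T  # (runs, nodes)
                ge += (null_x >= x_obs[None, :]).sum(axis=0)
                gt_obs += (null_x < x_obs[None, :]).sum(axis=0)
                lt_obs += (null_x > x_obs[None, :]).sum(axis=0)
                total += null_x.sum(axis=0)
            null_mean = total / cfg.runs
            p_more = (ge + 1) / (cfg.runs + 1)
            p_less = ((cfg.runs - lt_obs) + 1) / (cfg.runs + 1)
            is_more = gt_obs / cfg.runs >= flag_fraction
            is_less = lt_obs / cfg.runs >= flag_fraction
        flags = np.where(is_more, "MORE", np.where(is_less & report_less, "LESS", ""))
        frame = pd.DataFrame(
            {
                "sample": str(name),
                "node_label": labels,
                "D_v": D_v,
                "n": n,
                "N": N,
                "X_v": x_obs,
                "null_mean": null_mean,
                "p_more": p_more,
                "p_less": p_less,
                "flag": flags,
            }
        )
        if bh_correction:
            from .signal import _bh_adjust

            frame["p_more_bh"] = _bh_adjust(frame["p_more"].to_numpy())
        rows.append(frame)
        more = [labels[i] for i in np.flatnonzero(is_more)]
        if more:
            flagged[str(name)] = more
    if skipped:
        warnings.warn(
            "empty samples skipped: " + ", ".join(map(str, skipped)), stacklevel=2
        )
    if not rows:
        raise ValueError("no nonempty sample to test")
    table = pd.concat(rows, ignore_index=True)
    return NodeEnrichment(table=table, flagged=flagged, nodes=node_map)


def annotate_tree(
    tree: Phylogeny,
    results: NodeEnrichment | Mapping[str, Sequence[str]],
    precision: int = 10,
) -> str:
    """Newick string with flagged nodes labeled ``MORE:<sample>``.

    Multiple samples flagging one node join as ``MORE:a|b`` with sample
    names sorted; unflagged nodes carry no label, so an empty flag set
    reproduces the plain Newick output.
    """
    flagged = results.flagged if isinstance(results, NodeEnrichment) else results
    node_map = (
        results.nodes
        if isinstance(results, NodeEnrichment)
        else tree.node_by_report_label()
    )
    per_node: dict[str, list[str]] = {}
    for sample, labs in flagged.items():
        for lab in labs:
            per_node.setdefault(lab, []).append(str(sample))
    node_labels = {
        node_map[lab]: "MORE:" + "|".join(sorted(samples))
        for lab, samples in per_node.items()
    }
    return tree.to_newick(node_labels=node_labels, precision=precision)
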