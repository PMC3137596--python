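"""Maximal dependence decomposition (MDD) of aligned site windows.

MDD recursively partitions a set of aligned positive windows into subgroups
with conserved motifs.  At each step it finds the flanking position whose
residue-group occupancy is most strongly dependent (by Pearson chi-square
over a 5x5 contingency table) on the other flanking positions, picks the
residue group driving that dependence, and splits the windows into those
that carry a group residue at the position and those that do not.  Recursion
stops when a subgroup is smaller than ``max_cluster_size``, when no pairwise
dependence exceeds the chi-square cutoff, or when a split would produce a
child below ``min_leaf_size``.

The 20 amino acids are collapsed into five biochemical groups (aliphatic,
polar-uncharged, acid, basic, aromatic), so each contingency table is 5x5
with 16 degrees of freedom; the default cutoff 34.3 is the upper 0.005
quantile of chi-square(16).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator, ClusterMixin

from .sequence_io import AMINO_ACIDS, SequenceWindow


class MDDError(ValueError):
    pass


@dataclass(frozen=True)
class AAGroupScheme:
    """Ordered partition of the 20 standard residues into 5 named groups."""

    groups: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        if len(self.groups) != 5:
            raise MDDError("exactly 5 residue groups are required")
        union: set[str] = set()
        for _, members in self.groups:
            if union & members:
                raise MDDError("residue groups must be disjoint")
            union |= members
        if union != set(AMINO_ACIDS):
            raise MDDError("groups must cover the 20 standard residues")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.groups]

    def group_index(self, residue: str) -> int | None:
        """Group index of a residue; None for pad / unknown symbols."""
        for i, (_, members) in enumerate(self.groups):
            if residue in members:
                return i
        return None

    def members(self, index: int) -> frozenset[str]:
        return self.groups[index][1]

    @classmethod
    def default(cls) -> "AAGroupScheme":
        """Reconstructed 5-group biochemical scheme.

        aliphatic AGILPV, polar-uncharged CMNQST, acid DE, basic HKR,
        aromatic FWY.  Override via :func:`read_group_scheme` if a different
        grouping is preferred.
        """
        return cls(
            groups=(
                ("aliphatic", frozenset("AGILPV")),
                ("polar_uncharged", frozenset("CMNQST")),
                ("acid", frozenset("DE")),
                ("basic", frozenset("HKR")),
                ("aromatic", frozenset("FWY")),
            )
        )


def read_group_scheme(path: str) -> AAGroupScheme:
    """Read a scheme file: ``group_name<TAB>residues``, 5 lines."""
    groups = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, residues = line.partition("\t")
            groups.append((name, frozenset(residues.strip())))
    return AAGroupScheme(groups=tuple(groups))


@dataclass
class MDDConfig:
    """Stopping and significance parameters for the decomposition."""

    max_cluster_size: int = 100
    chi2_threshold: float = 34.3
    significance: float = 0.005
    df: int = 16
    min_leaf_size: int = 15

    def __post_init__(self) -> None:
        if self.chi2_threshold <= 0 or self.max_cluster_size <= 0:
            raise MDDError("thresholds must be positive")


def chi2_critical(p_upper: float, df: int) -> float:
    """Inverse upper-tail chi-square quantile."""
    if not 0.0 < p_upper < 1.0:
        raise MDDError(f"tail probability must lie in (0, 1), got {p_upper}")
    if df < 1:
        raise MDDError(f"degrees of freedom must be >= 1, got {df}")
    return float(chi2_dist.isf(p_upper, df))


@dataclass
class ContingencyTable:
    """5x5 residue-group co-occurrence counts between two window positions."""

    counts: np.ndarray
    position_i: int
    position_j: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def contingency(
    windows: Sequence[SequenceWindow],
    i: int,
    j: int,
    scheme: AAGroupScheme,
) -> ContingencyTable:
    """Co-occurrence counts of residue groups at signed offsets ``i``, ``j``.

    Windows whose residue at either position is a pad or unknown symbol are
    excluded from the table.
    """
    if i == 0 or j == 0 or i == j:
        raise MDDError(f"invalid position pair ({i}, {j})")
    if not windows:
        raise MDDError("no windows")
    counts = np.zeros((5, 5), dtype=int)
    for w in windows:
        gi = scheme.group_index(w.residue_at(i))
        gj = scheme.group_index(w.residue_at(j))
        if gi is None or gj is None:
            continue
        counts[gi, gj] += 1
    return ContingencyTable(counts=counts, position_i=i, position_j=j)


def chi2_stat(table: ContingencyTable | np.ndarray) -> float:
    """Pearson chi-square statistic of a contingency table.

    Expected counts are ``row_sum * col_sum / total``; cells with zero
    expectation contribute nothing.  No continuity correction.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    total = counts.sum()
    if total == 0:
        return 0.0
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            expected > 0, (counts - expected) ** 2 / expected, 0.0
        )
    return float(terms.sum())


# ---------------------------------------------------------------------------
# Tree structure


@dataclass
class MDDNode:
    """One node of the decomposition tree.

    Split nodes carry the (position, group) test and two children; leaves
    carry their member windows, a per-position motif summary, and a
    depth-first leaf id.
    """

    position: int | None = None
    group: int | None = None
    group_name: str | None = None
    chi2_evidence: float = 0.0
    present_child: "MDDNode | None" = None
    absent_child: "MDDNode | None" = None
    members: list[SequenceWindow] = field(default_factory=list)
    leaf_id: int | None = None
    motif_summary: dict[int, str] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.position is None

    def leaves(self) -> list["MDDNode"]:
        if self.is_leaf:
            return [self]
        return self.present_child.leaves() + self.absent_child.leaves()


@dataclass
class MDDTree:
    root: MDDNode
    n: int
    scheme: AAGroupScheme
    config: MDDConfig

    def leaves(self) -> list[MDDNode]:
        return self.root.leaves()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())


def _has_group_residue(
    window: SequenceWindow, position: int, group: int, scheme: AAGroupScheme
) -> bool:
    return scheme.group_index(window.residue_at(position)) == group


def _chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    return chi2_stat(np.array([[a, b], [c, d]]))


def _select_group(
    windows: Sequence[SequenceWindow],
    i_star: int,
    positions: Sequence[int],
    scheme: AAGroupScheme,
) -> int:
    """Pick the residue group at ``i_star`` driving the dependence.

    For each group g, the windows are partitioned by presence/absence of a
    group-g residue at ``i_star``; the score of g is the sum over all other
    positions j and groups h of the 2x2 chi-square between that partition
    and presence of a group-h residue at j.  Ties break by group order.
    """
    best_group, best_score = 0, -1.0
    for g in range(5):
        present = np.array(
            [_has_group_residue(w, i_star, g, scheme) for w in windows]
        )
        score = 0.0
        for j in positions:
            if j == i_star:
                continue
            for h in range(5):
                at_j = np.array(
                    [_has_group_residue(w, j, h, scheme) for w in windows]
                )
                a = int(np.sum(present & at_j))
                b = int(np.sum(present & ~at_j))
                c = int(np.sum(~present & at_j))
                d = int(np.sum(~present & ~at_j))
                score += _chi2_2x2(a, b, c, d)
        if score > best_score:
            best_group, best_score = g, score
    return best_group


def max_dependence(
    windows: Sequence[SequenceWindow],
    scheme: AAGroupScheme,
    cfg: MDDConfig,
) -> tuple[int, int, float] | None:
    """Find the flanking position with maximal chi-square dependence.

    The dependence score of position i is the sum of pairwise chi-square
    statistics chi2(i, j) over the other flanking positions j, counting only
    pairs exceeding ``cfg.chi2_threshold``.  Returns ``(position, group,
    max pairwise statistic)`` or None when no pair is significant.
    """
    if not windows:
        return None
    n = windows[0].n
    positions = [p for p in range(-n, n + 1) if p != 0]
    if len(positions) < 2:
        return None
    pair_stats: dict[tuple[int, int], float] = {}
    for i in positions:
        for j in positions:
            if i < j:
                stat = chi2_stat(contingency(windows, i, j, scheme))
                pair_stats[(i, j)] = stat
                pair_stats[(j, i)] = stat
    scores = {}
    for i in positions:
        sig = [
            pair_stats[(i, j)]
            for j in positions
            if j != i and pair_stats[(i, j)] > cfg.chi2_threshold
        ]
        scores[i] = sum(sig)
    i_star = max(positions, key=lambda i: (scores[i], -abs(i), i))
    if scores[i_star] <= 0.0:
        return None
    evidence = max(
        pair_stats[(i_star, j)] for j in positions if j != i_star
    )
    g_star = _select_group(windows, i_star, positions, scheme)
    return i_star, g_star, evidence


def _summarise_motif(
    windows: Sequence[SequenceWindow], scheme: AAGroupScheme, min_frac: float = 0.6
) -> dict[int, str]:
    """Dominant residue group per flanking position (>= min_frac occupancy)."""
    if not windows:
        return {}
    n = windows[0].n
    summary = {}
    for p in range(-n, n + 1):
        if p == 0:
            continue
        counts = np.zeros(5)
        for w in windows:
            g = scheme.group_index(w.residue_at(p))
            if g is not None:
                counts[g] += 1
        top = int(counts.argmax())
        if counts[top] / len(windows) >= min_frac:
            summary[p] = scheme.names[top]
    return summary


def mdd_cluster(
    positives: Sequence[SequenceWindow],
    scheme: AAGroupScheme | None = None,
    cfg: MDDConfig | None = None,
) -> MDDTree:
    """Recursively decompose positive windows into motif subgroups."""
    if not positives:
        raise MDDError("need at least one positive window")
    scheme = scheme or AAGroupScheme.default()
    cfg = cfg or MDDConfig()
    n = positives[0].n

    def split(windows: list[SequenceWindow]) -> MDDNode:
        if len(windows) < cfg.max_cluster_size:
            return MDDNode(members=windows)
        found = max_dependence(windows, scheme, cfg)
        if found is None:
            return MDDNode(members=windows)
        i_star, g_star, evidence = found
        present = [
            w for w in windows if _has_group_residue(w, i_star, g_star, scheme)
        ]
        absent = [
            w for w in windows if not _has_group_residue(w, i_star, g_star, scheme)
        ]
        if len(present) < cfg.min_leaf_size or len(absent) < cfg.min_leaf_size:
            return MDDNode(members=windows)
        return MDDNode(
            position=i_star,
            group=g_star,
            group_name=scheme.names[g_star],
            chi2_evidence=evidence,
            present_child=split(present),
            absent_child=split(absent),
        )

    root = split(list(positives))
    for k, leaf in enumerate(root.leaves(), 1):
        leaf.leaf_id = k
        leaf.motif_summary = _summarise_motif(leaf.members, scheme)
    return MDDTree(root=root, n=n, scheme=scheme, config=cfg)


def route(window: SequenceWindow, tree: MDDTree) -> int:
    """Deterministically descend the tree; returns the leaf id."""
    node = tree.root
    while not node.is_leaf:
        if _has_group_residue(window, node.position, node.group, tree.scheme):
            node = node.present_child
        else:
            node = node.absent_child
    return node.leaf_id


# ---------------------------------------------------------------------------
# Serialization


def _node_to_dict(node: MDDNode) -> dict:
    if node.is_leaf:
        return {
            "leaf_id": node.leaf_id,
            "members": [list(w.source) for w in node.members],
            "motif_summary": {str(k): v for k, v in node.motif_summary.items()},
        }
    return {
        "position": node.position,
        "group": node.group,
        "group_name": node.group_name,
        "chi2_evidence": node.chi2_evidence,
        "present": _node_to_dict(node.present_child),
        "absent": _node_to_dict(node.absent_child),
    }


def tree_to_json(tree: MDDTree) -> str:
    payload = {
        "n": tree.n,
        "config": {
            "max_cluster_size": tree.config.max_cluster_size,
            "chi2_threshold": tree.config.chi2_threshold,
            "significance": tree.config.significance,
            "df": tree.config.df,
            "min_leaf_size": tree.config.min_leaf_size,
        },
        "scheme": [
            [name, sorted(members)] for name, members in tree.scheme.groups
        ],
        "root": _node_to_dict(tree.root),
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def _node_from_dict(d: dict) -> MDDNode:
    if "leaf_id" in d:
        return MDDNode(
            leaf_id=d["leaf_id"],
            motif_summary={int(k): v for k, v in d.get("motif_summary", {}).items()},
        )
    return MDDNode(
        position=d["position"],
        group=d["group"],
        group_name=d["group_name"],
        chi2_evidence=d["chi2_evidence"],
        present_child=_node_from_dict(d["present"]),
        absent_child=_node_from_dict(d["absent"]),
    )


def tree_from_json(text: str) -> MDDTree:
    """Rebuild a tree from JSON; leaf member windows are not restored."""
    payload = json.loads(text)
    scheme = AAGroupScheme(
        groups=tuple(
            (name, frozenset(members)) for name, members in payload["scheme"]
        )
    )
    cfg = MDDConfig(**payload["config"])
    return MDDTree(
        root=_node_from_dict(payload["root"]),
        n=payload["n"],
        scheme=scheme,
        config=cfg,
    )


def motif_summary_table(tree: MDDTree) -> pd.DataFrame:
    rows = []
    for leaf in tree.leaves():
        if leaf.motif_summary:
            motif = ";".join(
                f"{p}:{g}" for p, g in sorted(leaf.motif_summary.items())
            )
        else:
            motif = "(none)"
        rows.append(
            {
                "leaf_id": leaf.leaf_id,
                "size": len(leaf.members),
                "motif": motif,
            }
        )
    return pd.DataFrame(rows)


class MDDClustering(BaseEstimator, ClusterMixin):
    """sklearn-style wrapper around :func:`mdd_cluster`.

    ``fit(X)`` expects a sequence of positive :class:`SequenceWindow`
    objects; after fitting, ``labels_`` holds each window's leaf id and
    ``tree_`` the decomposition.  ``predict`` routes unseen windows.
    """

    def __init__(
        self,
        max_cluster_size: int = 100,
        chi2_threshold: float = 34.3,
        min_leaf_size: int = 15,
        scheme: AAGroupScheme | None = None,
    ) -> None:
        self.max_cluster_size = max_cluster_size
        self.chi2_threshold = chi2_threshold
        self.min_leaf_size = min_leaf_size
        self.scheme = scheme

    def fit(self, X: Sequence[SequenceWindow], y=None) -> "MDDClustering":
        cfg = MDDConfig(
            max_cluster_size=self.max_cluster_size,
            chi2_threshold=self.chi2_threshold,
            min_leaf_size=self.min_leaf_size,
        )
        self.tree_ = mdd_cluster(X, scheme=self.scheme, cfg=cfg)
        self.labels_ = np.array([route(w, self.tree_) for w in X])
        return self

    def predict(self, X: Sequence[SequenceWindow]) -> np.ndarray:
        return np.array([route(w, self.tree_) for w in X])
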