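"""Functional node activities: network branches, majority functions, group tests.

The learned network is split into branches (connected pieces obtained by
repeatedly removing the edge of maximal betweenness), each branch is
assigned the majority function among its annotated members, and the
per-sample "functional node activity" of a branch is the mean value of the
member features whose own annotation matches the branch's majority label.
Activities are compared between two sample groups with a two-sided
Mann-Whitney U test and Benjamini-Hochberg correction across nodes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .ggm import DecomposableGraph
from .omics import OmicsMatrix, SampleAnnotation

logger = logging.getLogger(__name__)


class ActivityError(ValueError):
    pass


@dataclass
class BranchPartition:
    """Partition of network vertices into branches with majority labels.

    ``dominant_label`` is None for branches with no annotated member (such
    branches are excluded from activities); ``label_tied`` flags branches
    where the majority was a tie broken lexicographically.
    """

    members: dict[int, list[str]]  # branch id -> feature ids
    dominant_label: dict[int, str | None] = field(default_factory=dict)
    label_fraction: dict[int, float] = field(default_factory=dict)
    label_tied: dict[int, bool] = field(default_factory=dict)
    annotation: dict[str, str] = field(default_factory=dict)

    @property
    def branch_of(self) -> dict[str, int]:
        return {f: b for b, fs in self.members.items() for f in fs}

    @property
    def n_branches(self) -> int:
        return len(self.members)

    def labeled_branches(self) -> list[int]:
        return [b for b in sorted(self.members) if self.dominant_label.get(b) is not None]


def branch_decompose(graph: DecomposableGraph, target_branches: int) -> BranchPartition:
    """Split the network into branches by iterated edge-betweenness removal.

    Girvan-Newman style: delete the edge of maximal edge betweenness
    (lexicographic tie-break) until the number of connected components
    reaches ``target_branches``.  Branch ids are assigned by the
    lexicographically smallest member.
    """
    n_vertices = graph.graph.number_of_nodes()
    if target_branches < 1:
        raise ActivityError("target_branches must be >= 1")
    if target_branches > n_vertices:
        raise ActivityError(
            f"target_branches {target_branches} exceeds vertex count {n_vertices}")
    g = graph.graph.copy()
    while nx.number_connected_components(g) < target_branches:
        btw = nx.edge_betweenness_centrality(g)
        best = max(
            btw.items(),
            key=lambda kv: (kv[1], tuple(sorted((str(kv[0][0]), str(kv[0][1])), reverse=True))),
        )
        # deterministic: among maximal-betweenness edges keep the lexicographically
        # smallest (the reverse-sorted key above makes max() pick it)
        cand = [e for e, b in btw.items() if b >= best[1] - 1e-12]
        edge = min(tuple(sorted(e, key=str)) for e in cand)
        g.remove_edge(*edge)
    comps = sorted((sorted(c, key=str) for c in nx.connected_components(g)),
                   key=lambda c: str(c[0]))
    members = {i: comp for i, comp in enumerate(comps)}
    return BranchPartition(members=members)


def partition_from_assignments(assignments: dict[str, int] | pd.Series
                               ) -> BranchPartition:
    """Build a partition from explicit feature -> branch-id assignments.

    Supports externally curated branch memberships (e.g. drawn by
    inspection of the exported network) in place of the automatic
    decomposition.
    """
    if isinstance(assignments, pd.Series):
        assignments = assignments.to_dict()
    members: dict[int, list[str]] = {}
    for f, b in assignments.items():
        members.setdefault(int(b), []).append(str(f))
    return BranchPartition(members={b: sorted(fs) for b, fs in sorted(members.items())})


def assign_function(partition: BranchPartition, annotation: dict[str, str] | pd.Series
                    ) -> BranchPartition:
    """Assign each branch the most frequent annotation label among members.

    Ties take the lexicographically smallest label and are flagged; a
    branch with no annotated member gets a null label.
    """
    if isinstance(annotation, pd.Series):
        annotation = annotation.dropna().to_dict()
    out = BranchPartition(members={b: list(fs) for b, fs in partition.members.items()},
                          annotation=dict(annotation))
    for b, fs in out.members.items():
        labels = [annotation[f] for f in fs if f in annotation]
        if not labels:
            out.dominant_label[b] = None
            out.label_fraction[b] = 0.0
            out.label_tied[b] = False
            continue
        counts = Counter(labels)
        top = max(counts.values())
        winners = sorted(l for l, c in counts.items() if c == top)
        out.dominant_label[b] = winners[0]
        out.label_fraction[b] = top / len(labels)
        out.label_tied[b] = len(winners) > 1
        if len(winners) > 1:
            logger.warning("branch %d: majority tie between %s; took %r", b, winners, winners[0])
    return out


def node_activity(matrix: OmicsMatrix, partition: BranchPartition,
                  matching_only: bool = True) -> pd.DataFrame:
    """Per-sample functional node activities (functional node x sample).

    The activity of a labeled branch is the arithmetic mean over the member
    features whose own annotation equals the branch's dominant label — not
    over all members (``matching_only=False`` averages every member
    instead).  Unlabeled branches are excluded.
    """
    if not matrix.fully_observed:
        raise ActivityError("node activities require a fully observed matrix")
    if not partition.dominant_label:
        raise ActivityError("partition has no function labels: run assign_function first")
    df = matrix.to_frame()
    rows, index, contributors = [], [], {}
    for b in partition.labeled_branches():
        label = partition.dominant_label[b]
        matching = [f for f in partition.members[b] if f in df.index
                    and (not matching_only
                         or partition.annotation.get(f) == label)]
        rows.append(df.loc[matching].mean(axis=0))
        name = f"branch{b}:{label}"
        index.append(name)
        contributors[name] = matching
    out = pd.DataFrame(rows, index=index)
    out.attrs["contributors"] = contributors
    return out


def compare_groups(activities: pd.DataFrame, annotation: SampleAnnotation,
                   method: str = "mannwhitney") -> pd.DataFrame:
    """Two-group comparison of node activities.

    Two-sided Mann-Whitney per node (Welch t-test behind ``method="ttest"``),
    Benjamini-Hochberg adjusted q across nodes, with the direction of the
    effect (sign of group2 mean minus group1 mean).
    """
    groups = annotation.groups()
    if len(groups) != 2:
        raise ActivityError(f"exactly two groups required, found {groups}")
    g1, g2 = groups
    s1 = [s for s in activities.columns if annotation.group.get(s) == g1]
    s2 = [s for s in activities.columns if annotation.group.get(s) == g2]
    if len(s1) < 3 or len(s2) < 3:
        raise ActivityError(f"each group needs >= 3 samples (got {len(s1)}, {len(s2)})")
    stats, ps, direction = [], [], []
    for node in activities.index:
        a, b = activities.loc[node, s1].to_numpy(), activities.loc[node, s2].to_numpy()
        if method == "mannwhitney":
            res = mannwhitneyu(a, b, alternative="two-sided")
            stats.append(float(res.statistic))
            ps.append(float(res.pvalue))
        elif method == "ttest":
            from scipy.stats import ttest_ind
            res = ttest_ind(a, b, equal_var=False)
            stats.append(float(res.statistic))
            ps.append(float(res.pvalue))
        else:
            raise ValueError(f"unknown method {method!r}")
        direction.append("up_in_" + str(g2) if b.mean() > a.mean() else "up_in_" + str(g1))
    q = multipletests(ps, method="fdr_bh")[1]
    return pd.DataFrame(
        {"statistic": stats, "p": ps, "q": q, "direction": direction},
        index=activities.index,
    )
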