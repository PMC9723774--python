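"""Post-denoising taxon consolidation and guild filtering.

Three steps mirror the study's bioinformatic post-processing: (1) ASVs
assigned to the same virtual taxon (VT) are merged by summing read counts;
(2) ASVs without a VT assignment are merged when they form a monophyletic
clade in which every pair exceeds a sequence-identity threshold (strictly
> 0.97 by default), the merged taxa being named ``add_cluster1``,
``add_cluster2``, ... in decreasing read abundance; (3) ITS2 taxa are
restricted to a target guild at accepted assignment confidences.

Merging is read-conserving: per-sample totals never change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import (
    CONFIDENCE_VOCAB,
    CommunityTable,
    TaxonAnnotation,
    normalise_token,
)

__all__ = [
    "MergeMap",
    "merge_by_vt",
    "cluster_unassigned",
    "name_clusters",
    "filter_guild",
]


@dataclass
class MergeMap:
    """Mapping raw ASV -> final taxon, with provenance per final taxon.

    Provenance tags: ``vt_assigned`` (merged under a virtual-taxon ID),
    ``clustered`` (merged as a monophyletic identity cluster), or
    ``singleton`` (passed through unchanged).
    """

    asv_to_taxon: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def members(self, taxon_id: str) -> list[str]:
        return sorted(
            a for a, t in self.asv_to_taxon.items() if t == taxon_id
        )

    def merged_with(self, other: "MergeMap") -> "MergeMap":
        """Compose: self maps raw -> mid, other maps mid -> final."""
        combined = MergeMap()
        for raw, mid in self.asv_to_taxon.items():
            combined.asv_to_taxon[raw] = other.asv_to_taxon.get(mid, mid)
        combined.provenance = {**self.provenance}
        for taxon, tag in other.provenance.items():
            if tag != "singleton" or taxon not in combined.provenance:
                combined.provenance[taxon] = tag
        for taxon in set(combined.asv_to_taxon.values()):
            combined.provenance.setdefault(taxon, "singleton")
        combined.provenance = {
            t: tag
            for t, tag in combined.provenance.items()
            if t in set(combined.asv_to_taxon.values())
        }
        return combined


def merge_by_vt(
    raw: CommunityTable, annotations: Sequence[TaxonAnnotation]
) -> tuple[CommunityTable, MergeMap]:
    """Merge ASVs sharing a virtual-taxon ID by summing their read counts.

    The merged taxon takes the VT ID as its name and the guild of its
    members; ASVs without a VT assignment pass through unchanged.  Column
    order: merged VTs in order of first member appearance, then the
    unassigned pass-through columns in their original order.
    """
    ann = {a.asv_id: a for a in annotations}
    missing = [t for t in raw.taxa if t not in ann]
    if missing:
        raise ValueError(f"no annotation for ASV(s): {missing[:5]}")
    merge = MergeMap()
    vt_members: dict[str, list[str]] = {}
    passthrough: list[str] = []
    for asv in raw.taxa:
        vt = ann[asv].vt_id
        if vt:
            vt_members.setdefault(vt, []).append(asv)
            merge.asv_to_taxon[asv] = vt
            merge.provenance[vt] = "vt_assigned"
        else:
            passthrough.append(asv)
            merge.asv_to_taxon[asv] = asv
            merge.provenance[asv] = "singleton"
    cols: dict[str, pd.Series] = {}
    guilds: dict[str, str] = {}
    for vt, members in vt_members.items():
        member_guilds = {raw.guilds[m] for m in members}
        if len(member_guilds) > 1:
            raise ValueError(
                f"VT {vt!r} merges ASVs of different guilds: {member_guilds}"
            )
        cols[vt] = raw.counts[members].sum(axis=1)
        guilds[vt] = member_guilds.pop()
    for asv in passthrough:
        cols[asv] = raw.counts[asv]
        guilds[asv] = raw.guilds[asv]
    merged = CommunityTable(pd.DataFrame(cols, index=raw.samples), guilds)
    return merged, merge


def _clade_tip_sets(tree: TreeNode) -> list[list[str]]:
    """Tip-name sets of every internal clade with >= 2 tips."""
    out = []
    for node in tree.traverse(include_self=True):
        if not node.is_tip():
            out.append(sorted(t.name for t in node.tips()))
    return out


def _all_pairs_exceed(
    tips: Sequence[str], identities: pd.DataFrame, threshold: float
) -> bool:
    sub = identities.loc[list(tips), list(tips)].to_numpy()
    iu = np.triu_indices(len(tips), k=1)
    return bool(np.all(sub[iu] > threshold))


def cluster_unassigned(
    raw: CommunityTable,
    tree: TreeNode,
    identities: pd.DataFrame,
    threshold: float = 0.97,
) -> tuple[CommunityTable, MergeMap]:
    """Merge unassigned ASVs in monophyletic clades of high identity.

    The tree spans exactly the unassigned ASVs.  Clades are visited from
    the root towards the tips; the first (hence maximal) clade whose tips
    all exceed the identity threshold pairwise becomes one merged taxon,
    and its subclades are not revisited.  Identity must be strictly
    greater than ``threshold``.  Tips never absorbed keep their own IDs.
    Merged taxa are named ``add_cluster1``, ``add_cluster2``, ... by
    decreasing total read abundance (ties broken lexicographically by
    member IDs) via :func:`name_clusters`.
    """
    tip_names = [t.name for t in tree.tips()]
    absent_tab = [t for t in tip_names if t not in set(raw.taxa)]
    if absent_tab:
        raise ValueError(
            f"tree tip(s) absent from count table: {absent_tab[:5]}"
        )
    absent_mat = [t for t in tip_names if t not in set(identities.index)]
    if absent_mat:
        raise ValueError(
            f"tree tip(s) absent from identity matrix: {absent_mat[:5]}"
        )

    clusters: list[list[str]] = []

    def visit(node: TreeNode) -> None:
        if node.is_tip():
            return
        tips = sorted(t.name for t in node.tips())
        if _all_pairs_exceed(tips, identities, threshold):
            clusters.append(tips)
            return
        for child in node.children:
            visit(child)

    visit(tree)

    merge = MergeMap()
    clustered = {t for c in clusters for t in c}
    cols: dict[str, pd.Series] = {}
    guilds: dict[str, str] = {}
    for asv in raw.taxa:
        if asv in clustered:
            continue
        cols[asv] = raw.counts[asv]
        guilds[asv] = raw.guilds[asv]
        merge.asv_to_taxon[asv] = asv
        merge.provenance[asv] = "singleton"
    for i, members in enumerate(clusters):
        tmp_id = f"__cluster_{i}"
        cols[tmp_id] = raw.counts[members].sum(axis=1)
        guilds[tmp_id] = raw.guilds[members[0]]
        for m in members:
            merge.asv_to_taxon[m] = tmp_id
        merge.provenance[tmp_id] = "clustered"
    merged = CommunityTable(pd.DataFrame(cols, index=raw.samples), guilds)
    return name_clusters(merged, merge)


def name_clusters(
    merged: CommunityTable, merge: MergeMap
) -> tuple[CommunityTable, MergeMap]:
    """Rename clustered taxa ``add_cluster<i>`` by decreasing read total.

    Deterministic: equal totals are ordered lexicographically by their
    sorted member-ASV IDs.
    """
    cluster_ids = [
        t for t, tag in merge.provenance.items() if tag == "clustered"
    ]
    totals = merged.counts[cluster_ids].sum(axis=0)
    order = sorted(
        cluster_ids, key=lambda t: (-int(totals[t]), merge.members(t))
    )
    rename = {old: f"add_cluster{i + 1}" for i, old in enumerate(order)}
    counts = merged.counts.rename(columns=rename)
    guilds = {rename.get(t, t): g for t, g in merged.guilds.items()}
    out_map = MergeMap(
        asv_to_taxon={
            a: rename.get(t, t) for a, t in merge.asv_to_taxon.items()
        },
        provenance={
            rename.get(t, t): tag for t, tag in merge.provenance.items()
        },
    )
    return CommunityTable(counts, guilds), out_map


def filter_guild(
    raw: CommunityTable,
    annotations: Sequence[TaxonAnnotation],
    target_guild: str,
    allowed_confidences: frozenset[str] | set[str] = CONFIDENCE_VOCAB,
) -> CommunityTable:
    """Keep taxa of one guild at accepted assignment confidences.

    Guild and confidence comparisons are case-insensitive after whitespace
    normalisation.  A taxon with no recorded confidence is kept on guild
    match alone (assignment without a stated confidence level).  Samples
    left without any reads are retained; an informational warning lists
    them.  An empty result is a warning, not an error.
    """
    ann = {a.asv_id: a for a in annotations}
    missing = [t for t in raw.taxa if t not in ann]
    if missing:
        raise ValueError(f"no annotation for taxon/taxa: {missing[:5]}")
    want_guild = normalise_token(target_guild)
    allowed = {normalise_token(c) for c in allowed_confidences}
    keep = []
    for t in raw.taxa:
        a = ann[t]
        if a.guild is None or normalise_token(a.guild) != want_guild:
            continue
        if a.guild_confidence is not None:
            if normalise_token(a.guild_confidence) not in allowed:
                continue
        keep.append(t)
    if not keep:
        warnings.warn(
            f"guild filter for {target_guild!r} retained no taxa",
            stacklevel=2,
        )
        return _EmptyCommunity(raw.samples)
    out = CommunityTable(raw.counts[keep], raw.guilds)
    empty_samples = out.all_zero_samples()
    if empty_samples:
        warnings.warn(
            f"{len(empty_samples)} sample(s) have no reads after the "
            f"{target_guild} filter: {empty_samples[:5]}",
            stacklevel=2,
        )
    return out


class _EmptyCommunity:
    """Degenerate zero-taxon result of a guild filter (warning case)."""

    def __init__(self, samples: Sequence[str]):
        self.counts = pd.DataFrame(index=list(samples))
        self.guilds: dict[str, str] = {}
        self.samples = list(samples)
        self.taxa: list[str] = []
        self.shape = (len(self.samples), 0)

    def all_zero_samples(self) -> list[str]:
        return list(self.samples)
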