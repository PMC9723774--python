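"""Per-treatment taxon sets and UpSet-style exclusive intersections.

A taxon belongs to a treatment's set when it is detected in at least one
sample of that treatment (treatments: plot composition x richness, up to
AM-1/2/4, EM-1/2/4, Both-2/4).  The exclusive intersection of a subset S
of treatments counts the taxa found in *exactly* the treatments of S and
no others, the semantics of an UpSet plot; exclusive sizes over all
non-empty subsets therefore partition the union of all sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import CommunityTable, SampleRecord, TaxonAnnotation

__all__ = [
    "IntersectionTable",
    "treatment_sets",
    "upset_matrix",
    "genus_composition",
]


@dataclass
class IntersectionTable:
    """Exclusive intersection sizes over a family of treatment sets."""

    treatments: list[str]
    set_sizes: dict[str, int]
    # (subset of treatments, exclusive intersection size), zero rows omitted,
    # sorted by size desc, then subset cardinality asc, then lexicographic.
    exclusive: list[tuple[tuple[str, ...], int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"treatments": "&".join(subset), "degree": len(subset),
                 "exclusive_size": size}
                for subset, size in self.exclusive
            ]
        )


def treatment_sets(
    table: CommunityTable, meta: Sequence[SampleRecord], guild: str
) -> dict[str, set[str]]:
    """Taxa of a guild detected in each treatment (count > 0 in >= 1 sample)."""
    sample_set = set(table.samples)
    presence = table.presence()
    sets: dict[str, set[str]] = {}
    guild_taxa = set(table.guild_taxa(guild))
    for r in meta:
        sets.setdefault(r.treatment, set())
        if r.sample_id not in sample_set:
            continue
        row = presence.loc[r.sample_id]
        sets[r.treatment] |= set(row.index[row]) & guild_taxa
    return sets


def upset_matrix(sets: Mapping[str, set[str]]) -> IntersectionTable:
    """Exclusive (UpSet) intersection sizes of the treatment sets."""
    treatments = sorted(sets)
    if not any(sets.values()):
        raise ValueError("all treatment sets are empty")
    universe: set[str] = set().union(*sets.values())
    pattern_counts: dict[tuple[str, ...], int] = {}
    for taxon in universe:
        membership = tuple(t for t in treatments if taxon in sets[t])
        pattern_counts[membership] = pattern_counts.get(membership, 0) + 1
    exclusive = sorted(
        pattern_counts.items(),
        key=lambda kv: (-kv[1], len(kv[0]), kv[0]),
    )
    return IntersectionTable(
        treatments=treatments,
        set_sizes={t: len(sets[t]) for t in treatments},
        exclusive=[(subset, size) for subset, size in exclusive],
    )


def genus_composition(
    sets: Mapping[str, set[str]],
    annotations: Sequence[TaxonAnnotation] | Mapping[str, str],
) -> dict[str, dict[str, int]]:
    """Counts of taxa per genus within each treatment set.

    ``annotations`` is either a list of per-taxon annotations or a direct
    taxon -> genus mapping; taxa without a genus are binned as
    ``unassigned``.  Genus counts per treatment sum to the set size.
    """
    if isinstance(annotations, Mapping):
        genus_of = dict(annotations)
    else:
        genus_of = {a.asv_id: a.genus for a in annotations}
    out: dict[str, dict[str, int]] = {}
    for treatment, taxa in sets.items():
        comp: dict[str, int] = {}
        for t in sorted(taxa):
            genus = genus_of.get(t) or "unassigned"
            comp[genus] = comp.get(genus, 0) + 1
        out[treatment] = comp
    return out
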