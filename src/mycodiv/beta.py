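"""Sørensen similarities and the mixture/monoculture pair comparison.

For each focal tree in a mixture plot two kinds of presence/absence
Sørensen similarities are extracted: (i) against the same species'
monoculture individual in the same block (``mixture_vs_monoculture``) and
(ii) against each different-species neighbour within the plot
(``target_vs_neighbour``).  Within each stratum (focal tree mycorrhizal
type x plot richness: AM-2, AM-4, EM-2, EM-4) the two groups are compared
with Wilcoxon's rank-sum test.  If fungal communities track host species,
monoculture pairs are more similar than neighbour pairs; if they track
the shared plot environment, the ordering reverses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CommunityTable, SampleRecord

__all__ = [
    "PairSimilarity",
    "soerensen",
    "extract_pairs",
    "compare_pair_groups",
]

#: Default strata: AMF analysed for AM focal trees, EMF for EM focal trees.
GUILD_FOCAL_TYPE = {"AMF": "AM", "EMF": "EM"}


@dataclass
class PairSimilarity:
    """One Sørensen comparison between two root samples."""

    focal_sample_id: str
    partner_sample_id: str
    category: str  # "mixture_vs_monoculture" or "target_vs_neighbour"
    stratum: str  # e.g. "AM-2"
    similarity: float


def soerensen(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Presence/absence Sørensen similarity, 2|A∩B| / (|A|+|B|).

    Undefined (NaN) when both sets are empty.
    """
    a, b = set(set_a), set(set_b)
    if not a and not b:
        warnings.warn("Sørensen similarity of two empty sets is undefined")
        return float("nan")
    return 2.0 * len(a & b) / (len(a) + len(b))


def extract_pairs(
    table: CommunityTable,
    meta: Sequence[SampleRecord],
    guild: str,
    focal_type: str | None = None,
) -> tuple[list[PairSimilarity], dict[str, int]]:
    """Extract the two categories of similarity pairs for one guild.

    Focal trees are mixture-plot samples whose host mycorrhizal type is
    ``focal_type`` (default: the guild's own type).  For each focal tree,
    one ``mixture_vs_monoculture`` pair with the same species' monoculture
    sample in the same block (skipped when that monoculture sample is
    absent), and one ``target_vs_neighbour`` pair per different-species
    sample in the same plot (each unordered pair once, attributed to a
    focal tree of ``focal_type``).  Pairs where either community is empty
    in the guild are dropped and counted.

    Returns the pairs plus a counter dict (monoculture pairs skipped for a
    missing partner, pairs dropped for empty communities).  Deterministic
    and invariant to sample order.
    """
    focal = focal_type or GUILD_FOCAL_TYPE[guild]
    sample_set = set(table.samples)
    meta = [r for r in meta if r.sample_id in sample_set]
    by_id = {r.sample_id: r for r in meta}
    communities = {
        r.sample_id: table.sample_taxa(r.sample_id, guild) for r in meta
    }
    # Same-block monoculture sample of each species.
    mono: dict[tuple[str, str], str] = {}
    for r in meta:
        if r.plot_richness == 1:
            mono[(r.tree_species, r.block)] = r.sample_id

    counters = {
        "monoculture_partner_missing": 0,
        "pairs_dropped_empty": 0,
    }
    pairs: list[PairSimilarity] = []

    mixtures = sorted(
        (r for r in meta if r.plot_richness > 1), key=lambda r: r.sample_id
    )
    # (i) mixture individual vs its same-block monoculture individual
    for r in mixtures:
        if r.host_myc_type != focal:
            continue
        partner = mono.get((r.tree_species, r.block))
        if partner is None:
            counters["monoculture_partner_missing"] += 1
            continue
        a, b = communities[r.sample_id], communities[partner]
        if not a or not b:
            counters["pairs_dropped_empty"] += 1
            continue
        pairs.append(
            PairSimilarity(
                focal_sample_id=r.sample_id,
                partner_sample_id=partner,
                category="mixture_vs_monoculture",
                stratum=f"{focal}-{r.plot_richness}",
                similarity=soerensen(a, b),
            )
        )

    # (ii) all unordered different-species pairs within each mixture plot,
    # attributed to a focal tree of the requested type.
    by_plot: dict[str, list[SampleRecord]] = {}
    for r in mixtures:
        by_plot.setdefault(r.plot_id, []).append(r)
    for plot_id in sorted(by_plot):
        recs = sorted(by_plot[plot_id], key=lambda r: r.sample_id)
        for r1, r2 in itertools.combinations(recs, 2):
            if r1.tree_species == r2.tree_species:
                continue
            if focal == r1.host_myc_type:
                f, p = r1, r2
            elif focal == r2.host_myc_type:
                f, p = r2, r1
            else:
                continue
            a, b = communities[f.sample_id], communities[p.sample_id]
            if not a or not b:
                counters["pairs_dropped_empty"] += 1
                continue
            pairs.append(
                PairSimilarity(
                    focal_sample_id=f.sample_id,
                    partner_sample_id=p.sample_id,
                    category="target_vs_neighbour",
                    stratum=f"{focal}-{f.plot_richness}",
                    similarity=soerensen(a, b),
                )
            )
    return pairs, counters


def compare_pair_groups(
    pairs: Sequence[PairSimilarity],
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of the two pair categories per stratum.

    Returns one row per stratum with group sizes, medians, the rank-sum
    statistic and the two-sided p-value.  Strata missing either category
    are skipped with a warning.
    """
    by_stratum: dict[str, list[PairSimilarity]] = {}
    for p in pairs:
        by_stratum.setdefault(p.stratum, []).append(p)
    rows = []
    for stratum in sorted(by_stratum):
        group = by_stratum[stratum]
        mono = [
            p.similarity
            for p in group
            if p.category == "mixture_vs_monoculture"
        ]
        neigh = [
            p.similarity for p in group if p.category == "target_vs_neighbour"
        ]
        if not mono or not neigh:
            warnings.warn(
                f"stratum {stratum}: missing a pair category, skipped"
            )
            continue
        mono_a, neigh_a = np.asarray(mono), np.asarray(neigh)
        if np.ptp(np.concatenate([mono_a, neigh_a])) == 0:
            w, p_val = float("nan"), 1.0
        else:
            res = stats.mannwhitneyu(
                mono_a,
                neigh_a,
                alternative="two-sided",
                use_continuity=True,
                method="auto",
            )
            w, p_val = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "stratum": stratum,
                "n_monoculture_pairs": len(mono),
                "n_neighbour_pairs": len(neigh),
                "median_monoculture": float(np.median(mono_a)),
                "median_neighbour": float(np.median(neigh_a)),
                "W": w,
                "p_value": p_val,
            }
        )
    return pd.DataFrame(rows)
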