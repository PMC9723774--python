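"""Observed vs expected per-plot fungal richness and its additivity analysis.

Observed richness of a mixture plot is the number of unique taxa (of one
guild) detected across all of the plot's root samples; expected richness
sums the monoculture richness of each component tree species.  If mixture
communities were simple unions of the component monoculture communities,
observed would equal expected (the 1:1 line); per-treatment Pearson
correlations and OLS regressions of observed on expected quantify the
departure, separately for AMF and EMF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CommunityTable, SampleRecord, treatment_label

__all__ = [
    "RichnessPair",
    "observed_plot_richness",
    "expected_plot_richness",
    "richness_pairs",
    "additivity_analysis",
]


@dataclass
class RichnessPair:
    """Observed and expected richness of one mixture plot for one guild."""

    plot_id: str
    treatment: str  # e.g. "AM-2", "Both-4"
    guild: str
    observed: int
    expected: int


def _plot_records(
    meta: Sequence[SampleRecord], plot_id: str
) -> list[SampleRecord]:
    recs = [r for r in meta if r.plot_id == plot_id]
    if not recs:
        raise ValueError(f"unknown plot {plot_id!r}")
    return recs


def observed_plot_richness(
    table: CommunityTable,
    meta: Sequence[SampleRecord],
    plot_id: str,
    guild: str,
) -> int:
    """Unique taxa of the guild detected across the plot's samples."""
    recs = _plot_records(meta, plot_id)
    union: set[str] = set()
    for r in recs:
        if r.sample_id in set(table.samples):
            union |= table.sample_taxa(r.sample_id, guild)
    return len(union)


def _monoculture_richness(
    table: CommunityTable,
    meta: Sequence[SampleRecord],
    species: str,
    guild: str,
    block: str,
    policy: str,
) -> float:
    """Richness contributed by one species' monoculture(s).

    ``same_block``: the monoculture plot in the mixture's block, falling
    back to the mean over all blocks when that plot is missing.
    ``mean``: mean over all monoculture plots of the species.
    """
    monos = [
        r
        for r in meta
        if r.tree_species == species and r.plot_richness == 1
    ]
    if not monos:
        raise ValueError(f"species {species!r} has no monoculture")
    by_plot: dict[str, list[SampleRecord]] = {}
    for r in monos:
        by_plot.setdefault(r.plot_id, []).append(r)
    plot_rich = {
        p: observed_plot_richness(table, meta, p, guild) for p in by_plot
    }
    if policy == "same_block":
        same = [
            p
            for p, recs in by_plot.items()
            if any(r.block == block for r in recs)
        ]
        if same:
            return float(np.mean([plot_rich[p] for p in same]))
        # fall through to the cross-block mean
    elif policy != "mean":
        raise ValueError(f"unknown monoculture policy {policy!r}")
    return float(np.mean(list(plot_rich.values())))


def expected_plot_richness(
    table: CommunityTable,
    meta: Sequence[SampleRecord],
    plot_id: str,
    guild: str,
    monoculture_policy: str = "same_block",
    deduplicate: bool = False,
) -> float:
    """Sum of component-species monoculture richness for a mixture plot.

    Plain summation by default (taxa shared between component monocultures
    count once per monoculture); ``deduplicate=True`` instead counts the
    union of the monoculture communities.  May be fractional under the
    mean policy; callers round half-up when an integer is needed.
    """
    recs = _plot_records(meta, plot_id)
    block = recs[0].block
    species = sorted({r.tree_species for r in recs})
    if deduplicate:
        union: set[str] = set()
        for sp in species:
            monos = [
                r
                for r in meta
                if r.tree_species == sp
                and r.plot_richness == 1
                and (monoculture_policy != "same_block" or r.block == block)
            ]
            if not monos:
                monos = [
                    r
                    for r in meta
                    if r.tree_species == sp and r.plot_richness == 1
                ]
            if not monos:
                raise ValueError(f"species {sp!r} has no monoculture")
            for r in monos:
                if r.sample_id in set(table.samples):
                    union |= table.sample_taxa(r.sample_id, guild)
        return float(len(union))
    total = 0.0
    for sp in species:
        total += _monoculture_richness(
            table, meta, sp, guild, block, monoculture_policy
        )
    return total


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def richness_pairs(
    table: CommunityTable,
    meta: Sequence[SampleRecord],
    guild: str,
    monoculture_policy: str = "same_block",
) -> list[RichnessPair]:
    """Observed/expected pairs for every mixture plot in the metadata."""
    plots: dict[str, SampleRecord] = {}
    for r in meta:
        if r.plot_richness > 1:
            plots.setdefault(r.plot_id, r)
    pairs = []
    for plot_id in sorted(plots):
        rec = plots[plot_id]
        obs = observed_plot_richness(table, meta, plot_id, guild)
        exp = expected_plot_richness(
            table, meta, plot_id, guild, monoculture_policy
        )
        pairs.append(
            RichnessPair(
                plot_id=plot_id,
                treatment=treatment_label(
                    rec.plot_myc_composition, rec.plot_richness
                ),
                guild=guild,
                observed=obs,
                expected=_round_half_up(exp),
            )
        )
    return pairs


def additivity_analysis(
    pairs: Sequence[RichnessPair], min_n: int = 3
) -> pd.DataFrame:
    """Per-treatment expected-vs-observed correlation and regression.

    Returns one row per treatment with n, df (= n - 2), Pearson r, its
    two-sided p-value, the OLS slope/intercept of observed on expected,
    and whether every point lies strictly below the 1:1 line.  Treatments
    with fewer than ``min_n`` pairs, or with zero variance in expected
    richness, are reported as untestable (NaN statistics) rather than
    raising.  P-values are unadjusted.  Order-invariant in ``pairs``.
    """
    rows = []
    by_treatment: dict[str, list[RichnessPair]] = {}
    for p in pairs:
        by_treatment.setdefault(p.treatment, []).append(p)
    for treatment in sorted(by_treatment):
        group = by_treatment[treatment]
        exp = np.array([p.expected for p in group], dtype=float)
        obs = np.array([p.observed for p in group], dtype=float)
        n = len(group)
        row = {
            "treatment": treatment,
            "guild": group[0].guild,
            "n": n,
            "df": n - 2,
            "pearson_r": np.nan,
            "p_value": np.nan,
            "slope": np.nan,
            "intercept": np.nan,
            "testable": False,
            "all_below_1to1": bool(np.all(obs < exp)),
        }
        if n >= min_n and np.ptp(exp) > 0 and np.ptp(obs) > 0:
            r, p_val = stats.pearsonr(exp, obs)
            slope, intercept = np.polyfit(exp, obs, 1)
            row.update(
                pearson_r=float(r),
                p_value=float(p_val),
                slope=float(slope),
                intercept=float(intercept),
                testable=True,
            )
        elif n >= min_n and np.ptp(exp) > 0:
            # observed constant: correlation undefined, regression flat
            slope, intercept = np.polyfit(exp, obs, 1)
            row.update(slope=float(slope), intercept=float(intercept))
        rows.append(row)
    return pd.DataFrame(rows)
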