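"""Phi specialisation coefficients and permutation-null standardised scores.

The phi coefficient of association between a taxon's presence/absence
pattern and a sample grouping (here: host tree mycorrhizal type) equals
the Pearson correlation of the two indicator vectors; with N samples, N_g
in-group samples, n occurrences and n_g in-group occurrences,

    phi = (N * n_g - n * N_g) / sqrt(n * N_g * (N - n) * (N - N_g)).

To avoid bias from generally rare taxa, each observed phi is standardised
against a null distribution obtained by randomly permuting the host-type
labels over samples (group sizes preserved; 100 permutations by default):

    score = (phi - mean(null phi)) / sd(null phi),

and a taxon is called a specialist when its score exceeds 3 (strictly).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CommunityTable, SampleRecord, treatment_label

__all__ = [
    "SpecialisationResult",
    "phi_coefficient",
    "null_phi_distribution",
    "null_standardised_score",
    "specialisation_scores",
    "classify_specialists",
    "compare_guild_specialisation",
]

#: Standard-deviation threshold above the null mean for a specialist call.
DEFAULT_THRESHOLD = 3.0
DEFAULT_N_NULL = 100

#: Which host tree type each fungal guild is scored against by default.
GUILD_TARGET_TYPE = {"AMF": "AM", "EMF": "EM"}


@dataclass
class SpecialisationResult:
    """Specialisation of one taxon within one stratum."""

    taxon_id: str
    guild: str
    stratum: str  # treatment, or "pooled"
    target_group: str  # host mycorrhizal type scored against
    phi: float  # NaN when undefined
    null_mean: float
    null_sd: float
    score: float  # NaN when undefined
    specialist: bool
    undefined: bool  # True when phi or score could not be computed


def _as_bool_arrays(
    presence: Sequence[bool], group: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(presence, dtype=bool)
    g = np.asarray(group, dtype=bool)
    if p.shape != g.shape:
        raise ValueError(
            f"length mismatch: presence has {p.size}, group has {g.size}"
        )
    if p.ndim != 1 or p.size < 2:
        raise ValueError("presence/group must be 1-D vectors of length >= 2")
    return p, g


def phi_coefficient(
    presence: Sequence[bool], group: Sequence[bool]
) -> float:
    """Phi association between presence and group membership.

    Equals the Pearson correlation of the two 0/1 indicator vectors.
    Returns NaN when the taxon is present in all or in no samples (zero
    variance makes the coefficient undefined).  Raises if the group
    vector has no contrast.
    """
    p, g = _as_bool_arrays(presence, group)
    n_samples = p.size
    n_group = int(g.sum())
    if n_group == 0 or n_group == n_samples:
        raise ValueError("group vector must contain both members and non-members")
    n_occ = int(p.sum())
    if n_occ == 0 or n_occ == n_samples:
        return float("nan")
    n_in = int((p & g).sum())
    num = n_samples * n_in - n_occ * n_group
    den = np.sqrt(
        float(n_occ)
        * n_group
        * (n_samples - n_occ)
        * (n_samples - n_group)
    )
    return float(num / den)


def _phi_many(presence: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Vectorised phi of one presence vector against many group vectors.

    ``groups`` has shape (k, N); all rows share the same group size.
    """
    n_samples = presence.size
    n_occ = int(presence.sum())
    n_group = int(groups[0].sum())
    n_in = groups @ presence.astype(np.int64)
    num = n_samples * n_in - n_occ * n_group
    den = np.sqrt(
        float(n_occ)
        * n_group
        * (n_samples - n_occ)
        * (n_samples - n_group)
    )
    return num / den


def _taxon_rng(seed: int, taxon_id: str, stratum: str) -> np.random.Generator:
    """Per-taxon substream so results are order-independent."""
    ss = np.random.SeedSequence(
        [
            int(seed) & 0x7FFFFFFF,
            zlib.crc32(taxon_id.encode()),
            zlib.crc32(stratum.encode()),
        ]
    )
    return np.random.default_rng(ss)


def null_phi_distribution(
    presence: np.ndarray,
    group: np.ndarray,
    n_null: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phi under ``n_null`` random permutations of the group labels."""
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    perms = np.empty((n_null, group.size), dtype=np.int64)
    base = group.astype(np.int64)
    for k in range(n_null):
        perms[k] = rng.permutation(base)
    return _phi_many(presence, perms)


def null_standardised_score(
    presence: Sequence[bool],
    group: Sequence[bool],
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Observed phi, permutation-null mean/SD and the standardised score.

    When the null SD is zero the score is 0 if the observed phi equals the
    null mean and NaN (undefined) otherwise.
    """
    p, g = _as_bool_arrays(presence, group)
    phi = phi_coefficient(p, g)
    if np.isnan(phi):
        return {
            "phi": float("nan"),
            "null_mean": float("nan"),
            "null_sd": float("nan"),
            "score": float("nan"),
        }
    if rng is None:
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    nulls = null_phi_distribution(p, g, n_null, rng)
    null_mean = float(np.mean(nulls))
    null_sd = float(np.std(nulls, ddof=1))
    if null_sd == 0:
        score = 0.0 if phi == null_mean else float("nan")
    else:
        score = (phi - null_mean) / null_sd
    return {
        "phi": phi,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "score": float(score),
    }


def _score_block(
    table: CommunityTable,
    meta_by_id: dict[str, SampleRecord],
    sample_ids: list[str],
    guild: str,
    stratum: str,
    target_type: str,
    n_null: int,
    seed: int,
    threshold: float,
) -> list[SpecialisationResult]:
    # Canonical sample order (sorted IDs) makes every statistic invariant
    # to the order samples arrive in.
    sample_ids = sorted(sample_ids)
    group = np.array(
        [meta_by_id[s].host_myc_type == target_type for s in sample_ids]
    )
    presence = table.counts.loc[sample_ids] > 0
    results = []
    degenerate_group = group.all() or not group.any()
    for taxon in table.guild_taxa(guild):
        pres = presence[taxon].to_numpy()
        if degenerate_group or pres.sum() in (0, pres.size):
            results.append(
                SpecialisationResult(
                    taxon, guild, stratum, target_type,
                    float("nan"), float("nan"), float("nan"), float("nan"),
                    specialist=False, undefined=True,
                )
            )
            continue
        rng = _taxon_rng(seed, taxon, stratum)
        res = null_standardised_score(
            pres, group, n_null=n_null, rng=rng
        )
        score = res["score"]
        results.append(
            SpecialisationResult(
                taxon, guild, stratum, target_type,
                res["phi"], res["null_mean"], res["null_sd"], score,
                specialist=bool(not np.isnan(score) and score > threshold),
                undefined=bool(np.isnan(score)),
            )
        )
    return results


def specialisation_scores(
    table: CommunityTable,
    meta: Sequence[SampleRecord],
    guild: str,
    mode: str = "pooled",
    target_type: str | None = None,
    n_null: int = DEFAULT_N_NULL,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    restrict_to_detected: bool = True,
) -> list[SpecialisationResult]:
    """Specialisation of every taxon of a guild to its host tree type.

    ``mode="pooled"`` computes one score per taxon over all samples in
    which the guild was detected at all (the respective tree type is the
    grouping; the null permutes the mycorrhizal-type labels of all
    samples).  ``mode="per_treatment"`` stratifies by treatment
    (composition x richness); strata containing a single host type yield
    undefined results for every taxon.
    """
    if mode not in ("pooled", "per_treatment"):
        raise ValueError("mode must be 'pooled' or 'per_treatment'")
    target = target_type or GUILD_TARGET_TYPE[guild]
    meta_by_id = {r.sample_id: r for r in meta}
    shared = [s for s in table.samples if s in meta_by_id]
    sub = table.subset_samples(shared).subset_guild(guild)
    if restrict_to_detected:
        # Analysis set per guild: samples with >= 1 read of that guild.
        nonzero = sub.counts.sum(axis=1) > 0
        sub = sub.subset_samples(list(sub.counts.index[nonzero]))
    results: list[SpecialisationResult] = []
    if mode == "pooled":
        results.extend(
            _score_block(
                sub, meta_by_id, sub.samples, guild, "pooled", target,
                n_null, seed, threshold,
            )
        )
    else:
        strata: dict[str, list[str]] = {}
        for s in sub.samples:
            r = meta_by_id[s]
            strata.setdefault(
                treatment_label(r.plot_myc_composition, r.plot_richness), []
            ).append(s)
        for stratum in sorted(strata):
            results.extend(
                _score_block(
                    sub, meta_by_id, strata[stratum], guild, stratum,
                    target, n_null, seed, threshold,
                )
            )
    return results


def classify_specialists(
    results: Sequence[SpecialisationResult],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[SpecialisationResult]:
    """(Re-)apply the specialist call: score strictly above the threshold."""
    out = []
    for r in results:
        specialist = bool(not np.isnan(r.score) and r.score > threshold)
        out.append(
            SpecialisationResult(
                r.taxon_id, r.guild, r.stratum, r.target_group,
                r.phi, r.null_mean, r.null_sd, r.score,
                specialist=specialist,
                undefined=bool(np.isnan(r.score)),
            )
        )
    return out


def results_frame(results: Sequence[SpecialisationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon_id": r.taxon_id,
                "guild": r.guild,
                "stratum": r.stratum,
                "target_group": r.target_group,
                "phi": r.phi,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "score": r.score,
                "specialist": r.specialist,
                "undefined": r.undefined,
            }
            for r in results
        ]
    )


def compare_guild_specialisation(
    amf_scores: Sequence[float], emf_scores: Sequence[float]
) -> dict[str, float]:
    """Wilcoxon rank-sum (continuity-corrected) AMF vs EMF score comparison.

    Returns the two-sided p, the one-sided p for the AMF > EMF direction,
    the rank-sum statistic and the difference of means.  All-tied inputs
    give p = 1 with a warning.
    """
    amf = np.asarray([s for s in amf_scores if not np.isnan(s)], dtype=float)
    emf = np.asarray([s for s in emf_scores if not np.isnan(s)], dtype=float)
    if amf.size == 0 or emf.size == 0:
        raise ValueError("both score lists must be non-empty")
    mean_diff = float(amf.mean() - emf.mean())
    if np.ptp(np.concatenate([amf, emf])) == 0:
        warnings.warn("all scores tied; rank-sum test is uninformative")
        return {
            "statistic": float("nan"),
            "p_two_sided": 1.0,
            "p_amf_greater": 1.0,
            "mean_difference": mean_diff,
        }
    # method="auto" mirrors R's wilcox.test: exact for small untied
    # samples, otherwise the continuity-corrected normal approximation.
    res_two = stats.mannwhitneyu(
        amf, emf, alternative="two-sided", use_continuity=True,
        method="auto",
    )
    res_one = stats.mannwhitneyu(
        amf, emf, alternative="greater", use_continuity=True,
        method="auto",
    )
    return {
        "statistic": float(res_two.statistic),
        "p_two_sided": float(res_two.pvalue),
        "p_amf_greater": float(res_one.pvalue),
        "mean_difference": mean_diff,
    }
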