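"""Faith's phylogenetic diversity and host/neighbour effect models.

Faith's PD of a sample is the total branch length of the minimal rooted
subtree spanning the taxa present in it (including the path to the root,
so a single taxon has positive PD; an empty sample has PD 0).

Per-sample PD of each fungal guild is then modelled against four fixed
terms - tree species identity of the target tree, whether the neighbour
trees include a different species, whether they include a different
mycorrhizal type, and plot tree-species richness - with random intercepts
for block and plot nested in block, separately for AM-tree and EM-tree
subsets.  Term significance is reported as Type II Wald chi-square tests.

Neighbour covariates are encoded at plot grain: a sample's neighbour
species (or mycorrhizal type) is "different" when its plot contains at
least one other species (or at least one species of the other type);
monoculture samples are "same"/"same".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from skbio import TreeNode

from .core import CommunityTable, SampleRecord

__all__ = [
    "PDRecord",
    "TermTest",
    "faith_pd",
    "pd_table",
    "richness_anova",
    "neighbour_covariates",
    "pd_mixed_model",
]


@dataclass
class PDRecord:
    """Faith's PD and richness of one sample for one guild."""

    sample_id: str
    guild: str
    pd: float
    richness: int


@dataclass
class TermTest:
    """Wald chi-square test of one fixed term in the PD mixed model."""

    response: str
    subset: str  # "AM" or "EM" target trees
    term: str
    df: int
    chi_square: float
    p_value: float
    model_note: str = ""  # non-empty when a fallback structure was used


def faith_pd(
    taxa: Iterable[str], tree: TreeNode, prune: bool = False
) -> float:
    """Rooted Faith's phylogenetic diversity of a taxon set.

    Sums the branch lengths of every edge on the paths from the present
    tips to the root (each edge counted once).  Empty set -> 0.  Taxa
    missing from the tree raise unless ``prune=True`` drops them.
    """
    taxa = set(taxa)
    if not taxa:
        return 0.0
    tip_index = {t.name: t for t in tree.tips()}
    missing = sorted(taxa - tip_index.keys())
    if missing:
        if not prune:
            raise ValueError(f"taxa missing from tree: {missing[:5]}")
        taxa -= set(missing)
        if not taxa:
            return 0.0
    seen: set[int] = set()
    total = 0.0
    for name in taxa:
        node = tip_index[name]
        while node.parent is not None and id(node) not in seen:
            seen.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return total


def pd_table(
    table: CommunityTable,
    tree: TreeNode,
    guild: str,
    prune: bool = False,
    include_empty: bool = False,
) -> list[PDRecord]:
    """Per-sample PD records for one guild.

    Samples without any detection of the guild are excluded by default
    (their PD is "absent", not zero); ``include_empty=True`` keeps them
    with PD 0.
    """
    records = []
    for sample in table.samples:
        present = table.sample_taxa(sample, guild)
        if not present and not include_empty:
            continue
        records.append(
            PDRecord(
                sample_id=sample,
                guild=guild,
                pd=faith_pd(present, tree, prune=prune),
                richness=len(present),
            )
        )
    return records


def richness_anova(
    values: Sequence[float], richness_level: Sequence[int]
) -> dict[str, object]:
    """One-way ANOVA of a per-sample quantity across richness levels."""
    values = np.asarray(values, dtype=float)
    levels = np.asarray(richness_level)
    if values.shape != levels.shape:
        raise ValueError("values and richness_level differ in length")
    uniq = sorted(set(levels.tolist()))
    if len(uniq) < 2:
        raise ValueError("need >= 2 richness levels")
    groups = [values[levels == u] for u in uniq]
    for u, g in zip(uniq, groups):
        if g.size < 2:
            raise ValueError(f"richness level {u} has fewer than 2 samples")
    f_stat, p = stats.f_oneway(*groups)
    k = len(groups)
    n = values.size
    return {
        "F": float(f_stat),
        "df_between": k - 1,
        "df_within": n - k,
        "p_value": float(p),
        "group_means": {u: float(g.mean()) for u, g in zip(uniq, groups)},
    }


def neighbour_covariates(meta: Sequence[SampleRecord]) -> pd.DataFrame:
    """Plot-grain neighbour encoding for every sample.

    ``neighbour_species_diff`` is 1 when the plot contains another tree
    species; ``neighbour_myc_diff`` is 1 when the plot contains a species
    of the other mycorrhizal type.  Monocultures are 0/0.
    """
    plot_species: dict[str, set[str]] = {}
    plot_types: dict[str, set[str]] = {}
    for r in meta:
        plot_species.setdefault(r.plot_id, set()).add(r.tree_species)
        plot_types.setdefault(r.plot_id, set()).add(r.host_myc_type)
    rows = []
    for r in meta:
        other_species = plot_species[r.plot_id] - {r.tree_species}
        other_types = plot_types[r.plot_id] - {r.host_myc_type}
        # Composition, not realised sampling, defines the neighbourhood:
        # fall back to the plot's declared composition for the type.
        myc_diff = bool(other_types) or (
            r.plot_myc_composition == "Both"
        )
        rows.append(
            {
                "sample_id": r.sample_id,
                "plot_id": r.plot_id,
                "block": r.block,
                "tree_species": r.tree_species,
                "host_myc_type": r.host_myc_type,
                "plot_richness": r.plot_richness,
                "neighbour_species_diff": int(
                    bool(other_species) or r.plot_richness > 1
                ),
                "neighbour_myc_diff": int(myc_diff),
            }
        )
    return pd.DataFrame(rows)


_FORMULA = (
    "pd ~ C(tree_species) + neighbour_species_diff "
    "+ neighbour_myc_diff + plot_richness"
)

_TERM_LABELS = {
    "C(tree_species)": "tree_species_target",
    "neighbour_species_diff": "neighbour_species_diff",
    "neighbour_myc_diff": "neighbour_myc_diff",
    "plot_richness": "plot_richness",
}


def _fit_mixed(data: pd.DataFrame):
    """Fit PD ~ fixed terms with the random structure fallback chain.

    Primary: random intercepts for block and for plot within block.
    Fallbacks when the fit fails or does not converge: (1) drop the block
    intercept (keep plot-in-block), (2) drop the plot component (keep the
    block intercept).  Returns (model, fit, note).
    """
    attempts = [
        ("", dict(re_formula="1", vc_formula={"plot_id": "0 + C(plot_id)"})),
        (
            "block intercept dropped (singular fit)",
            dict(re_formula="0", vc_formula={"plot_id": "0 + C(plot_id)"}),
        ),
        ("plot component dropped (singular fit)", dict(re_formula="1")),
    ]
    last_err: Exception | None = None
    for note, kwargs in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    _FORMULA, data, groups="block", **kwargs
                )
                fit = model.fit(reml=True)
            if fit.converged and np.all(np.isfinite(fit.fe_params)):
                cov = fit.cov_params().iloc[
                    : len(fit.fe_params), : len(fit.fe_params)
                ]
                if np.all(np.isfinite(cov.to_numpy())):
                    return model, fit, note
        except (np.linalg.LinAlgError, ValueError) as err:  # pragma: no cover
            last_err = err
    raise RuntimeError(f"mixed model could not be fitted: {last_err}")


def pd_mixed_model(
    pd_records: Sequence[PDRecord],
    meta: Sequence[SampleRecord],
    subset: str,
    response_guild: str,
) -> tuple[list[TermTest], pd.DataFrame]:
    """Mixed-model term tests of guild PD within one tree-type subset.

    Fits PD on target tree species identity, neighbour-species and
    neighbour-mycorrhizal-type contrasts and plot richness, with random
    intercepts for block and plot-in-block, on the samples of ``subset``
    ("AM" or "EM") target trees.  Returns per-term Type II Wald chi-square
    tests and a table of group means of PD by the neighbour-type contrast
    (to read off the direction of a neighbour effect).
    """
    if subset not in ("AM", "EM"):
        raise ValueError("subset must be 'AM' or 'EM'")
    cov_df = neighbour_covariates(meta).set_index("sample_id")
    rows = []
    for rec in pd_records:
        if rec.sample_id not in cov_df.index:
            continue
        c = cov_df.loc[rec.sample_id]
        if c["host_myc_type"] != subset:
            continue
        rows.append(
            {
                "sample_id": rec.sample_id,
                "pd": rec.pd,
                "tree_species": c["tree_species"],
                "neighbour_species_diff": int(c["neighbour_species_diff"]),
                "neighbour_myc_diff": int(c["neighbour_myc_diff"]),
                "plot_richness": float(c["plot_richness"]),
                "plot_id": c["plot_id"],
                "block": c["block"],
            }
        )
    data = pd.DataFrame(rows)
    if data.empty:
        raise ValueError(f"no {response_guild} PD samples in subset {subset}")
    if data["plot_id"].nunique() < 2 or data["block"].nunique() < 2:
        raise ValueError("need samples from >= 2 plots and >= 2 blocks")
    if np.ptp(data["pd"].to_numpy()) == 0:
        # Constant response: every term has zero explained variance.
        tests = [
            TermTest(
                response=f"{response_guild} PD",
                subset=subset,
                term=label,
                df=(data["tree_species"].nunique() - 1
                    if name == "C(tree_species)" else 1),
                chi_square=0.0,
                p_value=1.0,
                model_note="constant response",
            )
            for name, label in _TERM_LABELS.items()
        ]
        means = data.groupby("neighbour_myc_diff")["pd"].agg(["mean", "count"])
        return tests, means.reset_index()

    model, fit, note = _fit_mixed(data)
    slices = model.data.design_info.term_name_slices
    fe = fit.fe_params.to_numpy()
    cov = fit.cov_params().to_numpy()[: fe.size, : fe.size]
    tests = []
    for name, label in _TERM_LABELS.items():
        if name not in slices:  # dropped (e.g. single species in subset)
            continue
        sl = slices[name]
        b = fe[sl]
        v = cov[sl, sl]
        try:
            chi2 = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            chi2 = float("nan")
        df = b.size
        p = float(stats.chi2.sf(chi2, df)) if np.isfinite(chi2) else float("nan")
        tests.append(
            TermTest(
                response=f"{response_guild} PD",
                subset=subset,
                term=label,
                df=df,
                chi_square=chi2,
                p_value=p,
                model_note=note,
            )
        )
    means = (
        data.groupby("neighbour_myc_diff")["pd"]
        .agg(["mean", "count"])
        .reset_index()
    )
    return tests, means


def term_tests_frame(tests: Sequence[TermTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "response": t.response,
                "subset": t.subset,
                "term": t.term,
                "df": t.df,
                "chi_square": t.chi_square,
                "p_value": t.p_value,
                "model_note": t.model_note,
            }
            for t in tests
        ]
    )
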