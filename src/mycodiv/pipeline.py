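"""End-to-end orchestration: simulate or load data, run every stage, write TSVs.

A run produces, per guild where applicable: the processed count table,
the observed/expected richness table, the specialisation score table and
the AMF-vs-EMF comparison, mixed-model term tests of phylogenetic
diversity, beta-diversity pair comparisons and UpSet intersection tables,
plus a JSON manifest of parameters, seed and per-stage counters.
Identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beta import compare_pair_groups, extract_pairs
from .core import (
    CommunityTable,
    SampleRecord,
    read_annotations,
    read_community_table,
    read_identity_matrix,
    read_metadata,
    read_tree,
    validate_dataset,
    write_annotations,
    write_community_table,
    write_metadata,
    write_identity_matrix,
    write_tree,
)
from .diversity import pd_mixed_model, pd_table, term_tests_frame
from .intersections import genus_composition, treatment_sets, upset_matrix
from .richness import additivity_analysis, richness_pairs
from .specialisation import (
    compare_guild_specialisation,
    results_frame,
    specialisation_scores,
)
from .synthetic import (
    CommunitySimParams,
    DesignParams,
    SplitParams,
    generate_design,
    simulate_asv_level,
    simulate_communities,
    simulate_phylogeny,
)
from .taxa import cluster_unassigned, filter_guild, merge_by_vt

logger = logging.getLogger("mycodiv")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat configuration of a full pipeline run.

    Either the four input paths (``counts``, ``meta``, ``annotations``
    plus per-guild trees) or ``preset="mydiv"`` (synthetic data) must be
    given.
    """

    preset: str | None = "mydiv"
    counts: str | None = None
    meta: str | None = None
    annotations: str | None = None
    amf_tree: str | None = None
    emf_tree: str | None = None
    identity_threshold: float = 0.97
    n_null: int = 100
    specialist_threshold: float = 3.0
    monoculture_policy: str = "same_block"
    allowed_confidences: tuple[str, ...] = (
        "possible",
        "probable",
        "highly probable",
    )
    seed: int = 0
    out_dir: str = "mycodiv_out"
    # synthetic-preset knobs (ignored when input paths are given)
    sim: CommunitySimParams = field(default_factory=CommunitySimParams)
    design: DesignParams = field(default_factory=DesignParams)
    split: SplitParams = field(default_factory=SplitParams)

    def __post_init__(self) -> None:
        has_paths = self.counts and self.meta
        if not has_paths and not self.preset:
            raise ValueError(
                "config needs either input paths (counts, meta) or a preset"
            )
        if not (0 < self.identity_threshold < 1):
            raise ValueError("identity_threshold must be in (0, 1)")
        if self.n_null < 2:
            raise ValueError("n_null must be >= 2")

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key, sub_cls in (
            ("sim", CommunitySimParams),
            ("design", DesignParams),
            ("split", SplitParams),
        ):
            if key in raw and isinstance(raw[key], Mapping):
                raw[key] = sub_cls(**raw[key])
        if "allowed_confidences" in raw:
            raw["allowed_confidences"] = tuple(raw["allowed_confidences"])
        return cls(**raw)

    def to_jsonable(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # a location, not an analysis parameter
        return d


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every analysis stage; write stage TSVs and a manifest.

    Returns a result bundle with the in-memory stage outputs and the
    manifest dict.  Any stage error aborts with the failing stage named;
    outputs of completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "stages": {},
    }
    bundle: dict[str, Any] = {"manifest": manifest}
    stage = "inputs"
    try:
        if config.counts and config.meta:
            table = read_community_table(config.counts)
            meta = read_metadata(config.meta)
            annotations = (
                read_annotations(config.annotations)
                if config.annotations
                else None
            )
            trees = {}
            if config.amf_tree:
                trees["AMF"] = read_tree(config.amf_tree)
            if config.emf_tree:
                trees["EMF"] = read_tree(config.emf_tree)
            truth = None
        else:
            table, meta, annotations, trees, truth = _synthesise(config, out)
        validate_dataset(table, meta)
        manifest["stages"]["inputs"] = {
            "n_samples": len(table.samples),
            "n_taxa": len(table.taxa),
            "n_amf_taxa": len(table.guild_taxa("AMF")),
            "n_emf_taxa": len(table.guild_taxa("EMF")),
        }
        bundle.update(table=table, meta=meta, truth=truth)

        stage = "taxon_processing"
        # Synthetic runs already exercise merging inside _synthesise; a
        # paths run with annotations applies the EMF guild filter here.
        if annotations is not None and config.counts:
            emf = filter_guild(
                table, annotations, "EMF",
                set(config.allowed_confidences),
            )
            manifest["stages"]["taxon_processing"] = {
                "n_emf_after_filter": len(emf.taxa)
            }

        stage = "richness_additivity"
        additivity = {}
        for guild in ("AMF", "EMF"):
            if not table.guild_taxa(guild):
                continue
            pairs = richness_pairs(
                table, meta, guild, config.monoculture_policy
            )
            analysis = additivity_analysis(pairs)
            _write_tsv(analysis, out / f"additivity_{guild}.tsv")
            additivity[guild] = analysis
        manifest["stages"]["richness_additivity"] = {
            g: int(df["n"].sum()) for g, df in additivity.items()
        }
        bundle["additivity"] = additivity

        stage = "specialisation"
        scores = {}
        for guild in ("AMF", "EMF"):
            if not table.guild_taxa(guild):
                continue
            res = specialisation_scores(
                table,
                meta,
                guild,
                mode="pooled",
                n_null=config.n_null,
                threshold=config.specialist_threshold,
                seed=config.seed,
            )
            df = results_frame(res)
            _write_tsv(df, out / f"specialisation_{guild}.tsv")
            scores[guild] = df
        comparison = None
        if "AMF" in scores and "EMF" in scores:
            comparison = compare_guild_specialisation(
                scores["AMF"]["score"].tolist(),
                scores["EMF"]["score"].tolist(),
            )
            _write_tsv(
                pd.DataFrame([comparison]), out / "guild_comparison.tsv"
            )
        manifest["stages"]["specialisation"] = {
            **{
                f"n_{g.lower()}_specialists": int(df["specialist"].sum())
                for g, df in scores.items()
            },
            **{
                f"{g.lower()}_mean_score": float(
                    df["score"].dropna().mean()
                )
                for g, df in scores.items()
            },
        }
        bundle.update(specialisation=scores, guild_comparison=comparison)

        stage = "diversity_models"
        term_tables = []
        for guild in ("AMF", "EMF"):
            tree = trees.get(guild)
            if tree is None or not table.guild_taxa(guild):
                continue
            records = pd_table(table, tree, guild, prune=True)
            for subset in ("AM", "EM"):
                try:
                    tests, _means = pd_mixed_model(
                        records, meta, subset, guild
                    )
                except (ValueError, RuntimeError) as err:
                    logger.warning(
                        "PD model %s/%s skipped: %s", guild, subset, err
                    )
                    continue
                term_tables.append(term_tests_frame(tests))
        if term_tables:
            pd_tests = pd.concat(term_tables, ignore_index=True)
            _write_tsv(pd_tests, out / "pd_term_tests.tsv")
            bundle["pd_term_tests"] = pd_tests
            manifest["stages"]["diversity_models"] = {
                "n_term_tests": int(len(pd_tests))
            }

        stage = "beta_diversity"
        beta_tables = {}
        for guild in ("AMF", "EMF"):
            if not table.guild_taxa(guild):
                continue
            pairs, counters = extract_pairs(table, meta, guild)
            comparison_df = compare_pair_groups(pairs)
            _write_tsv(comparison_df, out / f"beta_{guild}.tsv")
            beta_tables[guild] = comparison_df
            manifest["stages"].setdefault("beta_diversity", {})[guild] = {
                "n_pairs": len(pairs),
                **counters,
            }
        bundle["beta"] = beta_tables

        stage = "intersections"
        upset_tables = {}
        for guild in ("AMF", "EMF"):
            if not table.guild_taxa(guild):
                continue
            sets = treatment_sets(table, meta, guild)
            upset = upset_matrix(sets)
            _write_tsv(upset.to_frame(), out / f"upset_{guild}.tsv")
            upset_tables[guild] = upset
        manifest["stages"]["intersections"] = {
            g: len(t.exclusive) for g, t in upset_tables.items()
        }
        bundle["upset"] = upset_tables
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle


def _synthesise(
    config: PipelineConfig, out: Path
) -> tuple[
    CommunityTable,
    list[SampleRecord],
    list,
    dict[str, Any],
    list,
]:
    """Generate the synthetic dataset of a preset run and write its inputs."""
    design_params = config.design
    meta = generate_design(design_params, seed=config.seed)
    final, truth = simulate_communities(meta, config.sim, seed=config.seed)

    # Exercise the consolidation stage on the AMF side: split to raw ASVs,
    # merge assigned ones by VT, cluster the unassigned by identity.
    amf = final.subset_guild("AMF")
    raw, annotations = simulate_asv_level(amf, config.split, seed=config.seed)
    merged, merge_map = merge_by_vt(raw, annotations)
    unassigned = [
        t for t, tag in merge_map.provenance.items() if tag == "singleton"
    ]
    if len(unassigned) >= 2:
        tree, ident = simulate_phylogeny(unassigned, seed=config.seed)
        merged, merge_map2 = cluster_unassigned(
            merged, tree, ident, config.identity_threshold
        )
    # Recombine with the EMF side (already at final-taxon resolution).
    emf = final.subset_guild("EMF")
    combined = CommunityTable(
        pd.concat([merged.counts, emf.counts], axis=1),
        {**merged.guilds, **emf.guilds},
    )

    trees = {}
    for guild in ("AMF", "EMF"):
        taxa = combined.guild_taxa(guild)
        if len(taxa) >= 2:
            trees[guild], _ = simulate_phylogeny(
                taxa, seed=config.seed + (1 if guild == "EMF" else 0)
            )
    write_metadata(meta, out / "synthetic_meta.tsv")
    write_community_table(combined, out / "synthetic_counts.tsv")
    write_annotations(annotations, out / "synthetic_annotations.tsv")
    for guild, tree in trees.items():
        write_tree(tree, out / f"synthetic_tree_{guild}.nwk")
    return combined, meta, annotations, trees, truth
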