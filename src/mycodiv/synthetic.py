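"""Synthetic MyDiv-like designs and fungal communities with known ground truth.

The generators emulate the structure of the tree-diversity experiment this
package analyses: 80 plots in two blocks crossing tree species richness
(1/2/4) with plot mycorrhizal composition (AM-only, EM-only, mixed), one
root sample per plot x tree species (200 before dropout), an AMF pool of
~62 virtual taxa and an EMF pool of ~174 ASVs, host-type-skewed
colonisation, and configurable specialist/generalist taxa.  Every generator
is deterministic under its seed, and the planted truth is returned so
downstream statistics can be tested for recovery.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import (
    AM_SPECIES,
    EM_SPECIES,
    CommunityTable,
    SampleRecord,
    TaxonAnnotation,
    validate_identity_matrix,
)

__all__ = [
    "DesignParams",
    "CommunitySimParams",
    "SplitParams",
    "TaxonTruth",
    "generate_design",
    "simulate_communities",
    "simulate_phylogeny",
    "simulate_asv_level",
]

# Synthetic genus pools used for annotations; sizes follow the 8 AMF and
# 16 EMF (7 ascomycete + 9 basidiomycete) genera observed in this system.
AMF_GENERA = (
    "Glomus",
    "Paraglomus",
    "Claroideoglomus",
    "Diversispora",
    "Acaulospora",
    "Scutellospora",
    "Archaeospora",
    "Ambispora",
)
EMF_GENERA = (
    "Tuber",
    "Peziza",
    "Tarzetta",
    "Pachyphlodes",
    "Geopora",
    "Helvella",
    "Wilcoxina",
    "Tomentella",
    "Thelephora",
    "Laccaria",
    "Hebeloma",
    "Sebacina",
    "Scleroderma",
    "Paxillus",
    "Entoloma",
    "Cenococcum",
)


def _subseed(master: int, *parts: str) -> np.random.SeedSequence:
    """Deterministic, order-independent per-entity seed derivation."""
    keys = [zlib.crc32(p.encode()) for p in parts]
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF, *keys])


@dataclass
class DesignParams:
    """Parameters of the experimental design generator.

    Defaults reproduce the study layout: 10 species each with two
    monocultures (one per block), 30 two-species and 30 four-species
    mixture plots split evenly over AM-only / EM-only / mixed
    compositions, and ~6% sample dropout (12 of 200 root samples could
    not be attributed to the correct tree and were excluded).
    """

    n_blocks: int = 2
    am_species: tuple[str, ...] = AM_SPECIES
    em_species: tuple[str, ...] = EM_SPECIES
    monocultures_per_species: int = 2
    n_two_species_plots: int = 30
    n_four_species_plots: int = 30
    sample_dropout: float = 0.06

    def __post_init__(self) -> None:
        if len(self.am_species) != 5 or len(self.em_species) != 5:
            raise ValueError("species pool must have exactly 5 AM and 5 EM names")
        if not (0 <= self.sample_dropout < 1):
            raise ValueError("sample_dropout must be in [0, 1)")
        for name in (
            "n_blocks",
            "monocultures_per_species",
            "n_two_species_plots",
            "n_four_species_plots",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def species_map(self) -> dict[str, str]:
        return {
            **{s: "AM" for s in self.am_species},
            **{s: "EM" for s in self.em_species},
        }


def _mixture_compositions(
    pool_am: Sequence[str], pool_em: Sequence[str], richness: int, comp: str
) -> list[tuple[str, ...]]:
    """All admissible species combinations for one treatment cell."""
    if comp == "AM":
        return [tuple(c) for c in itertools.combinations(pool_am, richness)]
    if comp == "EM":
        return [tuple(c) for c in itertools.combinations(pool_em, richness)]
    half = richness // 2
    return [
        tuple(a) + tuple(e)
        for a in itertools.combinations(pool_am, half)
        for e in itertools.combinations(pool_em, half)
    ]


def generate_design(
    params: DesignParams = DesignParams(), seed: int = 0
) -> list[SampleRecord]:
    """Generate plots, assign species mixtures and emit one sample per tree.

    Mixture compositions are drawn uniformly from the admissible
    combinations of the treatment's pool(s); block assignment is balanced
    within each treatment cell; within a block a composition is never
    repeated (raises if a cell requests more plots than distinct
    combinations x blocks allow).  Dropout removes each sample
    independently at the configured rate.
    """
    rng = np.random.default_rng(_subseed(seed, "design"))
    species_map = params.species_map
    records: list[SampleRecord] = []
    plot_counter = itertools.count(1)

    def add_plot(block: str, species: tuple[str, ...], comp: str) -> None:
        plot_id = f"P{next(plot_counter):03d}"
        richness = len(species)
        for sp in species:
            short = "".join(w[:2] for w in sp.split()[:2])
            records.append(
                SampleRecord(
                    sample_id=f"{plot_id}_{short}",
                    plot_id=plot_id,
                    block=block,
                    tree_species=sp,
                    host_myc_type=species_map[sp],
                    plot_richness=richness,
                    plot_myc_composition=comp,
                )
            )

    blocks = [f"B{i + 1}" for i in range(params.n_blocks)]

    # Monocultures: one per species per block (two per species by default).
    for sp in params.am_species + params.em_species:
        for i in range(params.monocultures_per_species):
            block = blocks[i % len(blocks)]
            add_plot(block, (sp,), species_map[sp])

    # Mixtures: split each richness level evenly over the three compositions.
    for richness, n_plots in (
        (2, params.n_two_species_plots),
        (4, params.n_four_species_plots),
    ):
        if n_plots == 0:
            continue
        if n_plots % 3:
            raise ValueError(
                f"{n_plots} {richness}-species plots cannot be split evenly "
                "over the AM / EM / Both compositions"
            )
        per_comp = n_plots // 3
        for comp in ("AM", "EM", "Both"):
            combos = _mixture_compositions(
                params.am_species, params.em_species, richness, comp
            )
            if per_comp > len(combos) * len(blocks):
                raise ValueError(
                    f"treatment {comp}-{richness}: {per_comp} plots requested "
                    f"but only {len(combos)} distinct compositions over "
                    f"{len(blocks)} blocks are available"
                )
            # Balanced over blocks; within a block draw distinct combos.
            base, extra = divmod(per_comp, len(blocks))
            for bi, block in enumerate(blocks):
                k = base + (1 if bi < extra else 0)
                idx = rng.choice(len(combos), size=k, replace=False)
                for i in sorted(idx):
                    add_plot(block, combos[i], comp)

    if not records:
        return records
    if params.sample_dropout > 0:
        keep = rng.random(len(records)) >= params.sample_dropout
        records = [r for r, k in zip(records, keep) if k]
    return records


@dataclass
class TaxonTruth:
    """Planted truth for one simulated taxon."""

    taxon_id: str
    guild: str  # "AMF" or "EMF"
    specialist: bool
    affinity_level: str  # "myc_type" or "species"
    affinity_target: str  # host mycorrhizal type or tree species name
    p_in: float  # occupancy in matching samples
    p_out: float  # occupancy elsewhere

    def matches(self, rec: SampleRecord) -> bool:
        if self.affinity_level == "myc_type":
            return rec.host_myc_type == self.affinity_target
        return rec.tree_species == self.affinity_target


@dataclass
class CommunitySimParams:
    """Occupancy/abundance model for the community simulator.

    Presence of taxon *t* in sample *s* is Bernoulli with probability
    ``p_in`` when the sample matches the taxon's affinity target and
    ``p_out`` otherwise; generalists use the same probability everywhere.
    Counts, conditional on presence, are Gamma-Poisson (negative binomial)
    with mean scaled to ``sequencing_depth`` and at least one read.

    The default specialist fractions plant the contrast observed in this
    system - AMF lean specialist, EMF lean generalist.
    """

    n_amf_taxa: int = 62
    n_emf_taxa: int = 174
    amf_specialist_fraction: float = 0.6
    emf_specialist_fraction: float = 0.2
    in_group_occupancy: float = 0.8
    out_group_occupancy: float = 0.05
    generalist_occupancy: float = 0.30
    affinity_level: str = "myc_type"  # or "species"
    abundance_dispersion: float = 0.5
    sequencing_depth: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "amf_specialist_fraction",
            "emf_specialist_fraction",
            "in_group_occupancy",
            "out_group_occupancy",
            "generalist_occupancy",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.in_group_occupancy < self.out_group_occupancy:
            raise ValueError(
                "in_group_occupancy must be >= out_group_occupancy"
            )
        if self.affinity_level not in ("myc_type", "species"):
            raise ValueError("affinity_level must be 'myc_type' or 'species'")
        if self.abundance_dispersion <= 0 or self.sequencing_depth <= 0:
            raise ValueError("dispersion and depth must be positive")


def _make_truth(
    params: CommunitySimParams, rng: np.random.Generator
) -> list[TaxonTruth]:
    truth: list[TaxonTruth] = []
    pools = {"AM": list(AM_SPECIES), "EM": list(EM_SPECIES)}
    for guild, n, frac, own_type in (
        ("AMF", params.n_amf_taxa, params.amf_specialist_fraction, "AM"),
        ("EMF", params.n_emf_taxa, params.emf_specialist_fraction, "EM"),
    ):
        prefix = "VTX" if guild == "AMF" else "EASV"
        for i in range(n):
            taxon_id = f"{prefix}{i + 1:05d}"
            specialist = bool(rng.random() < frac)
            if specialist:
                if params.affinity_level == "species":
                    target = str(rng.choice(pools[own_type]))
                else:
                    target = own_type
                truth.append(
                    TaxonTruth(
                        taxon_id,
                        guild,
                        True,
                        params.affinity_level,
                        target,
                        params.in_group_occupancy,
                        params.out_group_occupancy,
                    )
                )
            else:
                # Generalist: identical occupancy on every host.
                p = params.generalist_occupancy
                truth.append(
                    TaxonTruth(
                        taxon_id, guild, False, "myc_type", own_type, p, p
                    )
                )
    return truth


def simulate_communities(
    design: Sequence[SampleRecord],
    params: CommunitySimParams = CommunitySimParams(),
    seed: int | None = None,
) -> tuple[CommunityTable, list[TaxonTruth]]:
    """Simulate a sample x taxon count table over a design, with truth.

    Reproducible under the seed and independent of sample order: every
    (taxon, sample) cell gets its own deterministic substream.
    """
    if not design:
        raise ValueError("empty design")
    master = params.seed if seed is None else seed
    truth = _make_truth(
        params, np.random.default_rng(_subseed(master, "truth"))
    )
    sample_ids = [r.sample_id for r in design]
    counts = np.zeros((len(design), len(truth)), dtype=np.int64)
    # Mean reads per present taxon, scaled so a sample's expected total is
    # roughly the nominal sequencing depth.
    exp_present = max(
        1.0,
        sum(
            (t.p_in + t.p_out) / 2 if t.specialist else t.p_in for t in truth
        )
        / 2,
    )
    mean_count = params.sequencing_depth / exp_present
    shape = 1.0 / params.abundance_dispersion
    for j, t in enumerate(truth):
        rng = np.random.default_rng(_subseed(master, "taxon", t.taxon_id))
        # Presence and counts drawn per sample in sorted-sample order so the
        # result is invariant to the order of the design list.
        order = np.argsort(sample_ids)
        probs = np.array(
            [t.p_in if t.matches(design[i]) else t.p_out for i in order]
        )
        present = rng.random(len(order)) < probs
        lam = rng.gamma(shape, mean_count / shape, size=len(order))
        c = rng.poisson(lam)
        c = np.where(present, np.maximum(c, 1), 0)
        counts[order, j] = c
    df = pd.DataFrame(
        counts, index=sample_ids, columns=[t.taxon_id for t in truth]
    )
    guilds = {t.taxon_id: t.guild for t in truth}
    return CommunityTable(df, guilds), truth


def simulate_phylogeny(
    taxa: Sequence[str], seed: int = 0, identity_floor: float = 0.9
) -> tuple[TreeNode, pd.DataFrame]:
    """Random rooted bifurcating tree plus a matched identity matrix.

    Branch lengths are exponential; pairwise identity is an affine
    decreasing map of patristic distance, ``1 - c * d`` with ``c`` chosen
    so identities span ``(identity_floor, 1)``.
    """
    taxa = [str(t) for t in taxa]
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa to build a tree")
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon IDs")
    rng = np.random.default_rng(_subseed(seed, "phylogeny", *sorted(taxa)))
    nodes = [TreeNode(name=t) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.exponential(0.05))
        b.length = float(rng.exponential(0.05))
        parent = TreeNode(children=[a, b])
        nodes.append(parent)
    tree = nodes[0]
    tree.length = None
    dm = tree.tip_tip_distances()
    d = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    d = d.loc[taxa, taxa]
    dmax = float(d.to_numpy().max())
    c = (1.0 - identity_floor) / dmax if dmax > 0 else 0.0
    ident = (1.0 - c * d).clip(lower=0.0)
    np.fill_diagonal(ident.values, 1.0)
    validate_identity_matrix(ident)
    return tree, ident


@dataclass
class SplitParams:
    """How final taxa are split into raw ASVs for the merge stage."""

    max_asvs_per_taxon: int = 3
    unassigned_fraction: float = 0.2  # taxa whose ASVs carry no VT ID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_asvs_per_taxon < 1:
            raise ValueError("max_asvs_per_taxon must be >= 1")
        if not (0 <= self.unassigned_fraction <= 1):
            raise ValueError("unassigned_fraction must be in [0, 1]")


def simulate_asv_level(
    table: CommunityTable,
    params: SplitParams = SplitParams(),
    seed: int | None = None,
) -> tuple[CommunityTable, list[TaxonAnnotation]]:
    """Split each taxon's counts over 1..k raw ASVs (multinomial).

    Per-sample totals are conserved exactly.  A configurable fraction of
    taxa is marked unassigned: their ASVs carry no virtual-taxon ID and
    must be recovered by phylogenetic clustering downstream.  Annotations
    carry genus (guild-appropriate pool) and, for EMF, an assignment
    confidence from the accepted vocabulary.
    """
    master = params.seed if seed is None else seed
    rng = np.random.default_rng(_subseed(master, "asv-split"))
    n_taxa = len(table.taxa)
    n_unassigned = int(round(params.unassigned_fraction * n_taxa))
    unassigned = set(
        np.array(table.taxa)[
            rng.choice(n_taxa, size=n_unassigned, replace=False)
        ]
    )
    raw_cols: dict[str, np.ndarray] = {}
    annotations: list[TaxonAnnotation] = []
    guild_map: dict[str, str] = {}
    asv_counter = itertools.count(1)
    for taxon in table.taxa:
        guild = table.guilds[taxon]
        k = (
            1
            if params.max_asvs_per_taxon == 1
            else int(rng.integers(1, params.max_asvs_per_taxon + 1))
        )
        weights = rng.dirichlet(np.ones(k))
        col = table.counts[taxon].to_numpy()
        split = np.vstack(
            [rng.multinomial(c, weights) for c in col]
        )  # samples x k
        genera = AMF_GENERA if guild == "AMF" else EMF_GENERA
        genus = str(genera[zlib.crc32(taxon.encode()) % len(genera)])
        for a in range(k):
            asv_id = f"ASV{next(asv_counter):05d}"
            raw_cols[asv_id] = split[:, a]
            guild_map[asv_id] = guild
            annotations.append(
                TaxonAnnotation(
                    asv_id=asv_id,
                    vt_id=None if taxon in unassigned else taxon,
                    genus=genus,
                    guild=guild,
                    guild_confidence=(
                        "highly probable" if guild == "EMF" else None
                    ),
                )
            )
    raw = pd.DataFrame(raw_cols, index=table.samples)
    return CommunityTable(raw, guild_map), annotations
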