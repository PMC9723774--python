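"""Domain types, TSV/Newick I/O and dataset validation.

The data model mirrors a root-mycorrhiza amplicon study on a tree-diversity
experiment: each *sample* is the fine-root community of one target tree
(one tree species in one plot), each *taxon* is an AMF virtual taxon or an
EMF amplicon sequence variant, and plots carry a crossed treatment of tree
species richness (1/2/4) and plot mycorrhizal composition (AM-only,
EM-only, or mixed).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "AM_SPECIES",
    "EM_SPECIES",
    "SPECIES_MYC_TYPE",
    "CONFIDENCE_VOCAB",
    "SampleRecord",
    "CommunityTable",
    "TaxonAnnotation",
    "ValidationReport",
    "read_community_table",
    "write_community_table",
    "read_metadata",
    "write_metadata",
    "read_annotations",
    "write_annotations",
    "read_identity_matrix",
    "write_identity_matrix",
    "read_tree",
    "write_tree",
    "validate_dataset",
    "validate_identity_matrix",
    "validate_tree",
    "normalise_token",
    "treatment_label",
]

# Tree species pools of the MyDiv experiment: five species whose roots are
# dominated by arbuscular mycorrhiza and five by ectomycorrhiza.
AM_SPECIES: tuple[str, ...] = (
    "Acer pseudoplatanus",
    "Aesculus hippocastanum",
    "Fraxinus excelsior",
    "Prunus avium",
    "Sorbus aucuparia",
)
EM_SPECIES: tuple[str, ...] = (
    "Betula pendula",
    "Carpinus betulus",
    "Fagus sylvatica",
    "Quercus petraea",
    "Tilia platyphyllos",
)
SPECIES_MYC_TYPE: dict[str, str] = {
    **{s: "AM" for s in AM_SPECIES},
    **{s: "EM" for s in EM_SPECIES},
}

#: FUNGuild-style assignment confidence levels accepted by default.
CONFIDENCE_VOCAB: frozenset[str] = frozenset(
    {"possible", "probable", "highly probable"}
)


def normalise_token(value: str) -> str:
    """Lower-case and collapse internal whitespace (guild/confidence matching)."""
    return " ".join(str(value).strip().lower().split())


def treatment_label(plot_myc_composition: str, plot_richness: int) -> str:
    """Treatment code combining plot composition and richness, e.g. ``AM-2``."""
    return f"{plot_myc_composition}-{plot_richness}"


@dataclass(frozen=True)
class SampleRecord:
    """One root sample: a single target tree in a single plot."""

    sample_id: str
    plot_id: str
    block: str
    tree_species: str
    host_myc_type: str  # "AM" or "EM"
    plot_richness: int  # 1, 2 or 4
    plot_myc_composition: str  # "AM", "EM" or "Both"

    def __post_init__(self) -> None:
        if self.host_myc_type not in ("AM", "EM"):
            raise ValueError(
                f"sample {self.sample_id!r}: host_myc_type must be AM or EM, "
                f"got {self.host_myc_type!r}"
            )
        if self.plot_richness not in (1, 2, 4):
            raise ValueError(
                f"sample {self.sample_id!r}: plot_richness must be 1, 2 or 4, "
                f"got {self.plot_richness!r}"
            )
        if self.plot_myc_composition not in ("AM", "EM", "Both"):
            raise ValueError(
                f"sample {self.sample_id!r}: plot_myc_composition must be "
                f"AM, EM or Both, got {self.plot_myc_composition!r}"
            )
        if self.plot_richness == 1 and self.plot_myc_composition == "Both":
            raise ValueError(
                f"sample {self.sample_id!r}: a monoculture plot cannot have "
                "composition 'Both'"
            )

    @property
    def treatment(self) -> str:
        return treatment_label(self.plot_myc_composition, self.plot_richness)


@dataclass
class TaxonAnnotation:
    """Annotation of one raw ASV: virtual-taxon assignment, genus, guild."""

    asv_id: str
    vt_id: str | None = None
    genus: str | None = None
    guild: str | None = None
    guild_confidence: str | None = None


class CommunityTable:
    """Sample x taxon count matrix with a guild label per taxon.

    Wraps a pandas DataFrame (rows = samples, columns = taxa, integer
    counts >= 0) plus a taxon -> guild mapping ("AMF" or "EMF").
    """

    def __init__(self, counts: pd.DataFrame, guilds: Mapping[str, str]):
        counts = counts.copy()
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        _check_unique(counts.index, "sample")
        _check_unique(counts.columns, "taxon")
        if counts.size == 0:
            raise ValueError("empty community table")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("community table contains non-numeric cells")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {counts.index[i]!r}, "
                f"taxon {counts.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValueError(
                f"non-integer count at sample {counts.index[i]!r}, "
                f"taxon {counts.columns[j]!r}"
            )
        self.counts = counts.astype(np.int64)
        guilds = {str(k): str(v) for k, v in guilds.items()}
        missing = [t for t in self.counts.columns if t not in guilds]
        if missing:
            raise ValueError(f"taxa without a guild label: {missing[:5]}")
        self.guilds: dict[str, str] = {t: guilds[t] for t in self.counts.columns}

    # -- basic accessors ---------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def guild_taxa(self, guild: str) -> list[str]:
        return [t for t in self.taxa if self.guilds[t] == guild]

    def subset_guild(self, guild: str) -> "CommunityTable":
        """Columns of one guild only (samples kept, even if all-zero)."""
        cols = self.guild_taxa(guild)
        if not cols:
            raise ValueError(f"no taxa with guild {guild!r}")
        return CommunityTable(self.counts[cols], self.guilds)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CommunityTable":
        return CommunityTable(self.counts.loc[list(sample_ids)], self.guilds)

    def presence(self) -> pd.DataFrame:
        """Boolean presence matrix (count > 0)."""
        return self.counts > 0

    def sample_taxa(self, sample_id: str, guild: str | None = None) -> set[str]:
        """Taxa present (count > 0) in one sample, optionally one guild."""
        row = self.counts.loc[sample_id]
        present = set(row.index[row > 0])
        if guild is not None:
            present = {t for t in present if self.guilds[t] == guild}
        return present

    def all_zero_samples(self) -> list[str]:
        row_sums = self.counts.sum(axis=1)
        return list(row_sums.index[row_sums == 0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.guilds == other.guilds

    def __repr__(self) -> str:
        n_s, n_t = self.shape
        return f"<CommunityTable {n_s} samples x {n_t} taxa>"


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} ID {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# File I/O.  Everything is tab-separated UTF-8 with a mandatory header row;
# trees are Newick.  Row/column order is preserved on read and write.
# ---------------------------------------------------------------------------

GUILD_ROW_LABEL = "#guild"


def read_community_table(
    path: str | Path,
    guilds: str | Path | Mapping[str, str] | None = None,
) -> CommunityTable:
    """Read a sample x taxon TSV.

    The guild labels come either from ``guilds`` (a mapping or the path of a
    two-column ``taxon<TAB>guild`` TSV) or from a row labelled ``#guild``
    embedded in the table itself.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ValueError(f"empty community table in {path}")
    _check_unique(df.columns, "taxon")
    _check_unique(df.index, "sample")
    guild_map: dict[str, str]
    if GUILD_ROW_LABEL in df.index:
        guild_map = df.loc[GUILD_ROW_LABEL].to_dict()
        df = df.drop(index=GUILD_ROW_LABEL)
    elif isinstance(guilds, Mapping):
        guild_map = dict(guilds)
    elif guilds is not None:
        gdf = pd.read_csv(guilds, sep="\t", dtype=str)
        guild_map = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1]))
    else:
        raise ValueError(
            "no guild labels: pass `guilds` or embed a '#guild' row"
        )
    try:
        counts = df.astype(np.int64)
    except ValueError:
        for s in df.index:
            for t in df.columns:
                try:
                    int(df.loc[s, t])
                except ValueError:
                    raise ValueError(
                        f"non-integer cell at sample {s!r}, taxon {t!r}: "
                        f"{df.loc[s, t]!r}"
                    ) from None
        raise
    return CommunityTable(counts, guild_map)


def write_community_table(
    table: CommunityTable, path: str | Path, embed_guilds: bool = True
) -> None:
    df = table.counts.astype(str)
    if embed_guilds:
        guild_row = pd.DataFrame(
            [table.guilds], index=[GUILD_ROW_LABEL], columns=df.columns
        )
        df = pd.concat([guild_row, df])
    df.to_csv(path, sep="\t", index_label="sample_id")


_META_COLUMNS = [
    "sample_id",
    "plot_id",
    "block",
    "tree_species",
    "host_myc_type",
    "plot_richness",
    "plot_myc_composition",
]


def read_metadata(
    path: str | Path,
    species_map: Mapping[str, str] = SPECIES_MYC_TYPE,
) -> list[SampleRecord]:
    """Read sample metadata and validate against the species -> type map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        rec = SampleRecord(
            sample_id=row.sample_id,
            plot_id=row.plot_id,
            block=row.block,
            tree_species=row.tree_species,
            host_myc_type=row.host_myc_type,
            plot_richness=int(row.plot_richness),
            plot_myc_composition=row.plot_myc_composition,
        )
        records.append(rec)
    validate_records(records, species_map)
    return records


def validate_records(
    records: Sequence[SampleRecord],
    species_map: Mapping[str, str] = SPECIES_MYC_TYPE,
) -> None:
    """Cross-record checks: unique IDs, species known and type-consistent."""
    _check_unique((r.sample_id for r in records), "sample")
    for r in records:
        if r.tree_species not in species_map:
            raise ValueError(
                f"sample {r.sample_id!r}: unknown tree species "
                f"{r.tree_species!r}"
            )
        expected = species_map[r.tree_species]
        if r.host_myc_type != expected:
            raise ValueError(
                f"sample {r.sample_id!r}: species {r.tree_species!r} is an "
                f"{expected} tree but host_myc_type={r.host_myc_type!r}"
            )


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "plot_id": r.plot_id,
                "block": r.block,
                "tree_species": r.tree_species,
                "host_myc_type": r.host_myc_type,
                "plot_richness": r.plot_richness,
                "plot_myc_composition": r.plot_myc_composition,
            }
            for r in records
        ],
        columns=_META_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


_ANN_COLUMNS = ["asv_id", "vt_id", "genus", "guild", "guild_confidence"]


def read_annotations(path: str | Path) -> list[TaxonAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")

    def _opt(v: object) -> str | None:
        return None if pd.isna(v) or v == "" else str(v)

    return [
        TaxonAnnotation(
            asv_id=str(row.asv_id),
            vt_id=_opt(row.vt_id),
            genus=_opt(row.genus),
            guild=_opt(row.guild),
            guild_confidence=_opt(row.guild_confidence),
        )
        for row in df.itertuples(index=False)
    ]


def write_annotations(
    annotations: Sequence[TaxonAnnotation], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "asv_id": a.asv_id,
                "vt_id": a.vt_id or "",
                "genus": a.genus or "",
                "guild": a.guild or "",
                "guild_confidence": a.guild_confidence or "",
            }
            for a in annotations
        ],
        columns=_ANN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_identity_matrix(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    validate_identity_matrix(m)
    return m


def write_identity_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    validate_identity_matrix(matrix)
    matrix.to_csv(path, sep="\t", index_label="asv_id", float_format="%.6f")


def validate_identity_matrix(m: pd.DataFrame, atol: float = 1e-6) -> None:
    if list(m.index) != list(m.columns):
        raise ValueError("identity matrix rows and columns differ")
    arr = m.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=atol):
        raise ValueError("identity matrix is not symmetric")
    if np.any(arr < -atol) or np.any(arr > 1 + atol):
        raise ValueError("identities outside [0, 1]")
    if not np.allclose(np.diag(arr), 1.0, atol=atol):
        raise ValueError("identity matrix diagonal is not 1")


def read_tree(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    validate_tree(tree)
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def validate_tree(tree: TreeNode) -> None:
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tip")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")


@dataclass
class ValidationReport:
    """Mismatches between a count table, metadata and an optional tree."""

    samples_only_in_table: list[str] = field(default_factory=list)
    samples_only_in_meta: list[str] = field(default_factory=list)
    taxa_missing_from_tree: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.samples_only_in_table
            or self.samples_only_in_meta
            or self.taxa_missing_from_tree
        )

    def messages(self) -> list[str]:
        out = []
        if self.samples_only_in_table:
            out.append(
                f"samples only in count table: {self.samples_only_in_table}"
            )
        if self.samples_only_in_meta:
            out.append(f"samples only in metadata: {self.samples_only_in_meta}")
        if self.taxa_missing_from_tree:
            out.append(f"taxa missing from tree: {self.taxa_missing_from_tree}")
        return out


def validate_dataset(
    table: CommunityTable,
    meta: Sequence[SampleRecord],
    tree: TreeNode | None = None,
    strict: bool = False,
) -> ValidationReport:
    """Cross-check table, metadata and tree; error on empty overlap.

    Side-effect free and idempotent: nothing is mutated, only reported.
    """
    table_samples = set(table.samples)
    meta_samples = {r.sample_id for r in meta}
    report = ValidationReport(
        samples_only_in_table=sorted(table_samples - meta_samples),
        samples_only_in_meta=sorted(meta_samples - table_samples),
    )
    if not (table_samples & meta_samples):
        raise ValueError("no overlapping samples between table and metadata")
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        report.taxa_missing_from_tree = sorted(set(table.taxa) - tips)
    if strict and not report.ok:
        raise ValueError("; ".join(report.messages()))
    return report
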