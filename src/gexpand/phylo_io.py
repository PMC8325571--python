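"""I/O layer: trees, metadata tables, and result writing.

All external representations of the analysis live here: rooted Newick trees
(via dendropy), tab-separated tip-metadata / abundance / MAG / enrichment
tables (via pandas), and the TSV + manifest outputs of a run.  The rest of
the package operates on the validated in-memory objects this module returns;
in particular the tree/metadata join is checked to be a bijection before any
downstream analysis can run.

Tables are tab-separated UTF-8 with ``#`` comment lines by default; CSV is
accepted through the ``sep`` argument.  Habitat labels are normalised
case-insensitively onto a closed six-value vocabulary (gut, oral, urogenital,
skin, airways, other); unknown labels map to ``other`` with a warning, and a
user-supplied alias mapping can route site names onto the vocabulary.
"""
from __future__ import annotations

import dataclasses
import datetime
import enum
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

logger = logging.getLogger("gexpand")

__all__ = [
    "Habitat",
    "TipRecord",
    "AnnotatedTree",
    "AbundanceRecord",
    "MAGRecord",
    "EnrichmentRecord",
    "PhyloIOError",
    "NewickParseError",
    "SchemaError",
    "JoinError",
    "read_newick",
    "write_newick",
    "read_tip_metadata",
    "join_tree_metadata",
    "read_abundance_table",
    "read_mag_table",
    "read_enrichment_table",
    "write_results",
]


class PhyloIOError(ValueError):
    """Base class for input validation failures."""


class NewickParseError(PhyloIOError):
    """Malformed Newick input (message carries the parser's location info)."""


class SchemaError(PhyloIOError):
    """A table is missing required columns or contains invalid rows."""


class JoinError(PhyloIOError):
    """Tree tips and metadata records are not in bijection."""


class Habitat(str, enum.Enum):
    """Closed body-site vocabulary."""

    GUT = "gut"
    ORAL = "oral"
    UROGENITAL = "urogenital"
    SKIN = "skin"
    AIRWAYS = "airways"
    OTHER = "other"

    @classmethod
    def normalize(cls, value: str, aliases: Mapping[str, str] | None = None) -> "Habitat":
        """Map a free-text site label onto the vocabulary (case-insensitive).

        Unknown labels become ``other`` with a logged warning.
        """
        key = str(value).strip().lower()
        if aliases:
            key = {k.lower(): v.lower() for k, v in aliases.items()}.get(key, key)
        try:
            return cls(key)
        except ValueError:
            logger.warning("unknown habitat %r mapped to 'other'", value)
            return cls.OTHER


@dataclasses.dataclass(frozen=True)
class TipRecord:
    """Per-genome metadata joined to one tree tip.

    ``assembly_size`` is the observed assembly length in bp; ``completeness``
    the single-copy-marker completeness estimate in percent, used downstream
    to correct assembly size toward true genome size.  ``pathogen_flag``
    marks lineages under active foodborne-pathogen surveillance.
    """

    tip_id: str
    genus: str
    habitat: Habitat
    assembly_size: int
    completeness: float
    species: str = ""
    pathogen_flag: bool = False

    def __post_init__(self) -> None:
        if self.assembly_size <= 0:
            raise PhyloIOError(f"tip {self.tip_id!r}: assembly_size must be > 0")
        if not (0.0 < self.completeness <= 100.0):
            raise PhyloIOError(
                f"tip {self.tip_id!r}: completeness must lie in (0, 100], got {self.completeness}"
            )


@dataclasses.dataclass(frozen=True)
class AbundanceRecord:
    species: str
    habitat: Habitat
    host_id: str
    rel_abundance: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rel_abundance <= 1.0):
            raise PhyloIOError(
                f"abundance of {self.species!r} in host {self.host_id!r} outside [0, 1]"
            )


@dataclasses.dataclass(frozen=True)
class MAGRecord:
    bin_id: str
    species_bin: str
    habitat: Habitat
    completeness: float
    genome_size: int
    contamination: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.completeness <= 100.0):
            raise PhyloIOError(f"MAG {self.bin_id!r}: completeness outside (0, 100]")
        if self.genome_size <= 0:
            raise PhyloIOError(f"MAG {self.bin_id!r}: genome_size must be > 0")


ENRICHMENT_SOURCES = (
    "prodigal_cluster",
    "COG",
    "Pfam",
    "TIGRFAM",
    "KEGG_module",
    "KEGG_class",
)


@dataclasses.dataclass(frozen=True)
class EnrichmentRecord:
    """Signed per-annotation enrichment score.

    Positive scores mean the annotation is disproportionately carried by
    gut genomes, negative by genomes from other body sites, zero means no
    enrichment either way.
    """

    annotation_id: str
    source: str
    score: float
    category_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise PhyloIOError(f"annotation {self.annotation_id!r}: score must be finite")


@dataclasses.dataclass
class AnnotatedTree:
    """A rooted tree whose tip set is in verified bijection with metadata."""

    tree: dendropy.Tree
    records: dict[str, TipRecord]

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def record(self, tip_id: str) -> TipRecord:
        return self.records[tip_id]

    def habitat(self, tip_id: str) -> Habitat:
        return self.records[tip_id].habitat

    @property
    def n_tips(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Trees


def read_newick(path: str | Path, default_branch_length: float | None = None) -> dendropy.Tree:
    """Read a rooted Newick tree, validating labels and branch lengths.

    Missing branch lengths are an error unless ``default_branch_length``
    supplies a value; negative lengths are always rejected (zero is allowed,
    as contrasts and Brownian simulation need only nonnegative lengths).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick in {path}: {exc}") from exc
    return _validate_tree(tree, default_branch_length)


def tree_from_string(newick: str, default_branch_length: float | None = None) -> dendropy.Tree:
    """Parse a Newick string with the same validation as :func:`read_newick`."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _validate_tree(tree, default_branch_length)


def _validate_tree(tree: dendropy.Tree, default_branch_length: float | None) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise PhyloIOError(f"duplicate tip labels: {dupes}")
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            if default_branch_length is None:
                raise PhyloIOError(
                    "tree has edges without branch lengths; "
                    "pass default_branch_length to accept them"
                )
            node.edge.length = float(default_branch_length)
        elif node.edge.length < 0:
            raise PhyloIOError(f"negative branch length {node.edge.length}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write Newick with 17 significant digits so read∘write is the identity."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    )
    Path(path).write_text(text)


# ---------------------------------------------------------------------------
# Tables

_TRUTHY = {"true", "t", "1", "yes", "y"}
_FALSY = {"false", "f", "0", "no", "n", ""}


def _parse_bool(value: object) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise ValueError(f"not a boolean: {value!r}")


def _read_table(path: str | Path, sep: str, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str).fillna("")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def read_tip_metadata(
    path: str | Path,
    sep: str = "\t",
    habitat_aliases: Mapping[str, str] | None = None,
) -> dict[str, TipRecord]:
    """Read the tip-metadata table into TipRecords keyed by tip id.

    Required columns: tip_id, genus, habitat, assembly_size, completeness.
    Optional: species, pathogen_flag.  Row-level problems (non-numeric sizes,
    completeness outside (0, 100], duplicate ids) are collected and reported
    together, naming the offending rows.
    """
    df = _read_table(path, sep, ["tip_id", "genus", "habitat", "assembly_size", "completeness"])
    records: dict[str, TipRecord] = {}
    bad_rows: list[str] = []
    for i, row in df.iterrows():
        try:
            tip_id = str(row["tip_id"]).strip()
            if not tip_id:
                raise ValueError("empty tip_id")
            if tip_id in records:
                raise ValueError(f"duplicate tip_id {tip_id!r}")
            records[tip_id] = TipRecord(
                tip_id=tip_id,
                genus=str(row["genus"]).strip(),
                species=str(row.get("species", "")).strip(),
                habitat=Habitat.normalize(row["habitat"], habitat_aliases),
                assembly_size=int(float(row["assembly_size"])),
                completeness=float(row["completeness"]),
                pathogen_flag=_parse_bool(row.get("pathogen_flag", "false")),
            )
        except (ValueError, PhyloIOError) as exc:
            bad_rows.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if bad_rows:
        raise SchemaError(f"{path}: invalid rows:\n  " + "\n  ".join(bad_rows))
    return records


def join_tree_metadata(tree: dendropy.Tree, records: Mapping[str, TipRecord]) -> AnnotatedTree:
    """Verify the tip/record bijection and return the annotated tree."""
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    rec_ids = set(records)
    orphan_tips = sorted(tips - rec_ids)
    orphan_records = sorted(rec_ids - tips)
    if orphan_tips or orphan_records:
        raise JoinError(
            f"tree/metadata join is not a bijection: tips without records "
            f"{orphan_tips}, records without tips {orphan_records}"
        )
    for node in tree.preorder_internal_node_iter():
        if len(node.child_nodes()) < 2:
            raise PhyloIOError("internal node with a single child (unifurcation)")
    return AnnotatedTree(tree=tree, records=dict(records))


def read_abundance_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a species × habitat × host relative-abundance table.

    Columns: species, habitat, host_id, rel_abundance.  Abundances must lie
    in [0, 1] and per-(host, habitat) totals may not exceed 1 (beyond a small
    rounding slack).
    """
    df = _read_table(path, sep, ["species", "habitat", "host_id", "rel_abundance"])
    out = pd.DataFrame(
        {
            "species": df["species"].str.strip(),
            "habitat": [Habitat.normalize(h).value for h in df["habitat"]],
            "host_id": df["host_id"].str.strip(),
            "rel_abundance": pd.to_numeric(df["rel_abundance"], errors="coerce"),
        }
    )
    if out["rel_abundance"].isna().any():
        bad = (out.index[out["rel_abundance"].isna()] + 2).tolist()
        raise SchemaError(f"{path}: non-numeric rel_abundance in rows {bad}")
    if ((out["rel_abundance"] < 0) | (out["rel_abundance"] > 1)).any():
        raise SchemaError(f"{path}: rel_abundance outside [0, 1]")
    totals = out.groupby(["host_id", "habitat"])["rel_abundance"].sum()
    if (totals > 1.0 + 1e-9).any():
        offending = totals[totals > 1.0 + 1e-9].index.tolist()
        raise SchemaError(f"{path}: per-(host, habitat) abundances exceed 1 for {offending}")
    return out


def read_mag_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a MAG metadata table (bin_id, species_bin, habitat, completeness,
    genome_size, optional contamination)."""
    df = _read_table(path, sep, ["bin_id", "species_bin", "habitat", "completeness", "genome_size"])
    out = pd.DataFrame(
        {
            "bin_id": df["bin_id"].str.strip(),
            "species_bin": df["species_bin"].str.strip(),
            "habitat": [Habitat.normalize(h).value for h in df["habitat"]],
            "completeness": pd.to_numeric(df["completeness"], errors="coerce"),
            "genome_size": pd.to_numeric(df["genome_size"], errors="coerce"),
        }
    )
    if "contamination" in df.columns:
        out["contamination"] = pd.to_numeric(df["contamination"], errors="coerce")
    bad = out["completeness"].isna() | out["genome_size"].isna()
    if bad.any():
        raise SchemaError(f"{path}: non-numeric completeness/genome_size in rows {(out.index[bad] + 2).tolist()}")
    if ((out["completeness"] <= 0) | (out["completeness"] > 100)).any():
        raise SchemaError(f"{path}: completeness outside (0, 100]")
    if (out["genome_size"] <= 0).any():
        raise SchemaError(f"{path}: non-positive genome_size")
    out["genome_size"] = out["genome_size"].astype(int)
    return out


def read_enrichment_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read an annotation-enrichment score table.

    Columns: annotation_id, source, score, optional category_flags
    (semicolon-separated set, e.g. ``CRISPR``).
    """
    df = _read_table(path, sep, ["annotation_id", "source", "score"])
    score = pd.to_numeric(df["score"], errors="coerce")
    if score.isna().any() or (~score.apply(math.isfinite)).any():
        raise SchemaError(f"{path}: non-finite enrichment scores")
    out = pd.DataFrame(
        {
            "annotation_id": df["annotation_id"].str.strip(),
            "source": df["source"].str.strip(),
            "score": score.astype(float),
            "category_flags": df.get("category_flags", pd.Series([""] * len(df))).fillna(""),
        }
    )
    return out


# ---------------------------------------------------------------------------
# Results


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: Mapping[str, object] | None = None,
    timestamp: bool = True,
) -> list[Path]:
    """Write result tables as TSV plus a JSON run manifest.

    Table rows are written in their given (already deterministic) order; the
    manifest records configuration, seeds and software version so a run can
    be reproduced byte-identically.  The manifest's ``timestamp`` field is the
    only output that varies between identically-configured runs.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, lineterminator="\n")
        written.append(p)
    payload: dict[str, object] = {"software": "gexpand", "version": __version__}
    if manifest:
        payload.update(manifest)
    if timestamp:
        payload["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    p = out / "run_manifest.json"
    p.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    written.append(p)
    return written
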