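"""Extraction of phylogenetically independent gut vs non-gut comparisons.

A comparison is anchored at an internal node whose child subtrees are each
"pure" for one side — entirely gut tips or entirely non-gut tips — with both
sides present among the children (reciprocal monophyly).  For multifurcating
anchors, pure-gut children are pooled against pure-non-gut children, but only
when *every* child is pure; a single mixed child disqualifies the node.  An
anchor's ancestors always see a mixed child, and its descendants are
single-sided, so the comparisons a tree yields are tip-disjoint by
construction: each contributes one statistically independent observation of
habitat-associated size divergence.

Polarisation asks which habitat is the derived state: if every tip in the
anchor's sister clade(s) is non-gut, the gut clade is nested within non-gut
diversity and the gut residency is inferred to be derived (and vice versa);
mixed sisters, or an anchor at the root, leave the comparison unpolarised.
"""
from __future__ import annotations

import dataclasses
import enum
import logging
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .phylo_io import AnnotatedTree, Habitat, TipRecord

logger = logging.getLogger("gexpand")

__all__ = [
    "Level",
    "Polarity",
    "IndependentComparison",
    "find_independent_comparisons",
    "polarize_comparison",
    "filter_pathogen_comparisons",
    "mag_species_comparisons",
    "comparisons_to_frame",
]


class Level(str, enum.Enum):
    CONGENERIC = "congeneric"
    CONSPECIFIC = "conspecific"
    MAG_SPECIES = "mag_species"


class Polarity(str, enum.Enum):
    GUT_DERIVED = "gut_derived"
    NONGUT_DERIVED = "nongut_derived"
    UNPOLARIZED = "unpolarized"


@dataclasses.dataclass(frozen=True)
class IndependentComparison:
    """One tip-disjoint gut vs non-gut clade pair.

    ``group`` is the taxonomic unit the comparison is nested in: the genus
    for congeneric comparisons, the species for conspecific ones, and the
    species-level bin for MAG comparisons.  ``anchor_index`` is the pre-order
    index of the anchoring internal node (None for MAG comparisons, which
    carry no within-species tree).
    """

    comparison_id: str
    group: str
    gut_tips: frozenset[str]
    nongut_tips: frozenset[str]
    nongut_habitats: frozenset[Habitat]
    polarity: Polarity
    level: Level
    anchor_index: int | None = None

    def __post_init__(self) -> None:
        if not self.gut_tips or not self.nongut_tips:
            raise ValueError("both sides of a comparison must be nonempty")
        if self.gut_tips & self.nongut_tips:
            raise ValueError("gut and non-gut tip sets overlap")

    @property
    def tips(self) -> frozenset[str]:
        return self.gut_tips | self.nongut_tips

    def stratum(self) -> str:
        """Habitat stratum: the single non-gut habitat, or 'mixed'."""
        if len(self.nongut_habitats) == 1:
            return next(iter(self.nongut_habitats)).value
        return "mixed"


def _preorder_index(tree: dendropy.Tree) -> dict[int, int]:
    return {id(node): i for i, node in enumerate(tree.preorder_node_iter())}


def find_independent_comparisons(
    atree: AnnotatedTree,
    level: Level | str = Level.CONGENERIC,
    genus_required: bool = True,
) -> list[IndependentComparison]:
    """Enumerate all reciprocally monophyletic gut/non-gut comparisons.

    Post-order traversal; a node anchors a comparison iff every child subtree
    is pure for one side, both sides occur, and (when ``genus_required``) all
    tips below share one genus — one species when ``level`` is conspecific.
    The result is ordered by the anchor's pre-order index and is tip-disjoint.
    """
    level = Level(level)
    if level is Level.MAG_SPECIES:
        raise ValueError("use mag_species_comparisons() for MAG tables")
    records = atree.records
    pre_index = _preorder_index(atree.tree)

    # Per-node rollup, computed in post-order: tip list, gut purity, taxa.
    info: dict[int, tuple[list[str], bool, bool, set[str], set[str]]] = {}
    for node in atree.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            rec = records[label]
            is_gut = rec.habitat is Habitat.GUT
            info[id(node)] = ([label], is_gut, not is_gut, {rec.genus}, {(rec.genus, rec.species)})
        else:
            tips: list[str] = []
            all_gut = True
            all_nongut = True
            genera: set[str] = set()
            species: set[str] = set()
            for child in node.child_nodes():
                t, g, ng, ge, sp = info[id(child)]
                tips.extend(t)
                all_gut &= g
                all_nongut &= ng
                genera |= ge
                species |= sp
            info[id(node)] = (tips, all_gut, all_nongut, genera, species)

    comparisons: list[IndependentComparison] = []
    anchors: list[dendropy.Node] = []
    for node in atree.tree.preorder_internal_node_iter():
        children = node.child_nodes()
        gut_children = []
        nongut_children = []
        pure = True
        for child in children:
            _, g, ng, _, _ = info[id(child)]
            if g:
                gut_children.append(child)
            elif ng:
                nongut_children.append(child)
            else:
                pure = False
                break
        if not pure or not gut_children or not nongut_children:
            continue
        _, _, _, genera, species = info[id(node)]
        if genus_required and len(genera) != 1:
            continue
        if level is Level.CONSPECIFIC and len(species) != 1:
            continue
        anchors.append(node)

    for node in anchors:
        gut_tips = frozenset(
            t for child in node.child_nodes() if info[id(child)][1] for t in info[id(child)][0]
        )
        nongut_tips = frozenset(
            t for child in node.child_nodes() if not info[id(child)][1] for t in info[id(child)][0]
        )
        genera = info[id(node)][3]
        species = info[id(node)][4]
        if level is Level.CONSPECIFIC:
            group = next(iter(species))[1] or next(iter(genera))
        else:
            group = next(iter(genera)) if len(genera) == 1 else "+".join(sorted(genera))
        comparisons.append(
            IndependentComparison(
                comparison_id=f"c{len(comparisons):04d}",
                group=group,
                gut_tips=gut_tips,
                nongut_tips=nongut_tips,
                nongut_habitats=frozenset(records[t].habitat for t in nongut_tips),
                polarity=_polarity_at(node, records),
                level=level,
                anchor_index=pre_index[id(node)],
            )
        )
    _assert_tip_disjoint(comparisons)
    return comparisons


def _polarity_at(anchor: dendropy.Node, records: Mapping[str, TipRecord]) -> Polarity:
    parent = anchor.parent_node
    if parent is None:
        return Polarity.UNPOLARIZED
    sister_habitats: set[bool] = set()
    for sib in parent.child_nodes():
        if sib is anchor:
            continue
        for leaf in sib.leaf_iter():
            sister_habitats.add(records[leaf.taxon.label].habitat is Habitat.GUT)
    if sister_habitats == {False}:
        return Polarity.GUT_DERIVED
    if sister_habitats == {True}:
        return Polarity.NONGUT_DERIVED
    return Polarity.UNPOLARIZED


def polarize_comparison(atree: AnnotatedTree, comparison: IndependentComparison) -> Polarity:
    """Re-derive the polarity of a comparison from its anchor's sister clades."""
    if comparison.anchor_index is None:
        return Polarity.UNPOLARIZED
    for i, node in enumerate(atree.tree.preorder_node_iter()):
        if i == comparison.anchor_index:
            under = {leaf.taxon.label for leaf in node.leaf_iter()}
            if under != set(comparison.tips):
                raise ValueError("anchor node does not match the comparison's tips")
            return _polarity_at(node, atree.records)
    raise ValueError(f"anchor index {comparison.anchor_index} not in tree")


def _assert_tip_disjoint(comparisons: Sequence[IndependentComparison]) -> None:
    seen: set[str] = set()
    for c in comparisons:
        overlap = seen & c.tips
        if overlap:
            raise AssertionError(f"comparisons share tips {sorted(overlap)}")
        seen |= c.tips


def filter_pathogen_comparisons(
    comparisons: Iterable[IndependentComparison],
    records: Mapping[str, TipRecord],
) -> tuple[list[IndependentComparison], list[IndependentComparison]]:
    """Split comparisons into (retained, excluded) by pathogen surveillance.

    A comparison is excluded iff any member tip is flagged as under active
    foodborne-pathogen surveillance.
    """
    retained: list[IndependentComparison] = []
    excluded: list[IndependentComparison] = []
    for c in comparisons:
        if any(records[t].pathogen_flag for t in c.tips):
            excluded.append(c)
        else:
            retained.append(c)
    logger.info(
        "pathogen filter: retained %d comparisons, excluded %d", len(retained), len(excluded)
    )
    return retained, excluded


def mag_species_comparisons(
    mags: pd.DataFrame,
    min_completeness: float = 90.0,
    max_contamination: float | None = None,
) -> list[IndependentComparison]:
    """Build intraspecific comparisons from a MAG table.

    MAGs are kept when completeness strictly exceeds ``min_completeness``
    (and, when given, contamination is strictly below ``max_contamination``);
    each species-level bin with at least one retained gut MAG and one
    retained non-gut MAG yields one comparison.  Bins carry no within-species
    tree, so phylogenetic independence holds across (not within) species.
    """
    df = mags[mags["completeness"] > min_completeness]
    if max_contamination is not None and "contamination" in df.columns:
        df = df[df["contamination"] < max_contamination]
    out: list[IndependentComparison] = []
    for species_bin, grp in df.groupby("species_bin", sort=True):
        gut = grp.loc[grp["habitat"] == Habitat.GUT.value, "bin_id"]
        nongut = grp.loc[grp["habitat"] != Habitat.GUT.value, "bin_id"]
        if gut.empty or nongut.empty:
            continue
        habs = frozenset(
            Habitat(h) for h in grp.loc[grp["habitat"] != Habitat.GUT.value, "habitat"]
        )
        out.append(
            IndependentComparison(
                comparison_id=f"m{len(out):04d}",
                group=str(species_bin),
                gut_tips=frozenset(gut),
                nongut_tips=frozenset(nongut),
                nongut_habitats=habs,
                polarity=Polarity.UNPOLARIZED,
                level=Level.MAG_SPECIES,
            )
        )
    return out


def comparisons_to_frame(comparisons: Sequence[IndependentComparison]) -> pd.DataFrame:
    """Tabular view with a stable column order, for TSV output."""
    rows = [
        {
            "comparison_id": c.comparison_id,
            "group": c.group,
            "level": c.level.value,
            "polarity": c.polarity.value,
            "stratum": c.stratum(),
            "n_gut": len(c.gut_tips),
            "n_nongut": len(c.nongut_tips),
            "gut_tips": ";".join(sorted(c.gut_tips)),
            "nongut_tips": ";".join(sorted(c.nongut_tips)),
            "nongut_habitats": ";".join(sorted(h.value for h in c.nongut_habitats)),
        }
        for c in comparisons
    ]
    cols = [
        "comparison_id",
        "group",
        "level",
        "polarity",
        "stratum",
        "n_gut",
        "n_nongut",
        "gut_tips",
        "nongut_tips",
        "nongut_habitats",
    ]
    return pd.DataFrame(rows, columns=cols)
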