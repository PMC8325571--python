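"""Shared fixtures: tiny hand-built annotated trees and random-tree helpers."""
from __future__ import annotations

import numpy as np
import pytest

from gexpand.phylo_io import AnnotatedTree, Habitat, TipRecord, join_tree_metadata, tree_from_string


def annotate(
    newick: str,
    habitats: dict[str, str],
    genera: dict[str, str] | None = None,
    species: dict[str, str] | None = None,
    sizes: dict[str, int] | None = None,
    completeness: dict[str, float] | None = None,
    pathogens: set[str] | None = None,
) -> AnnotatedTree:
    """Build an AnnotatedTree from a Newick string and per-tip attributes.

    Unspecified attributes default to genus 'X', species '', 3 Mb assemblies
    at 100% completeness, no pathogen flags.
    """
    tree = tree_from_string(newick, default_branch_length=1.0)
    records = {}
    for leaf in tree.leaf_node_iter():
        t = leaf.taxon.label
        records[t] = TipRecord(
            tip_id=t,
            genus=(genera or {}).get(t, "X"),
            species=(species or {}).get(t, ""),
            habitat=Habitat.normalize(habitats[t]),
            assembly_size=(sizes or {}).get(t, 3_000_000),
            completeness=(completeness or {}).get(t, 100.0),
            pathogen_flag=t in (pathogens or set()),
        )
    return join_tree_metadata(tree, records)


@pytest.fixture
def cherry_pair() -> AnnotatedTree:
    """Two gut tips sister to two oral tips, one genus: one forced comparison."""
    return annotate(
        "((g1:1,g2:1):1,(o1:1,o2:1):1);",
        {"g1": "gut", "g2": "gut", "o1": "oral", "o2": "oral"},
    )


def random_annotated_tree(
    rng: np.random.Generator,
    n_tips: int,
    p_gut: float = 0.45,
    n_genera: int = 2,
) -> AnnotatedTree:
    """Random Yule tree with random habitat and genus labels, for oracles."""
    from gexpand.synthetic_data import simulate_tree

    tree = simulate_tree(n_tips, 1.0, rng)
    habitats = {}
    genera = {}
    non_gut = ["oral", "urogenital", "skin", "airways"]
    for leaf in tree.leaf_node_iter():
        t = leaf.taxon.label
        habitats[t] = "gut" if rng.random() < p_gut else non_gut[rng.integers(len(non_gut))]
        genera[t] = f"G{rng.integers(n_genera)}"
    records = {
        t: TipRecord(
            tip_id=t,
            genus=genera[t],
            habitat=Habitat.normalize(habitats[t]),
            assembly_size=int(rng.integers(2_000_000, 6_000_000)),
            completeness=float(rng.uniform(90, 100)),
        )
        for t in habitats
    }
    return join_tree_metadata(tree, records)
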