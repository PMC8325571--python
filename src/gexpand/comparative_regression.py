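"""Phylogenetically independent contrasts and abundance–size regressions.

Closely related species are not independent samples: under Brownian-motion
(BM) trait evolution their values covary in proportion to shared ancestry.
Felsenstein's pruning algorithm turns n tip values on a rooted tree into
n − 1 standardized contrasts that are i.i.d. under BM, so ordinary
regression through the origin on contrasts is free of phylogenetic
pseudoreplication.  The same model can be fit as generalized least squares
with covariance C_ij = shared root-to-MRCA path length; the GLS slope (with
an intercept, which plays the role of the phylogenetic mean) is algebraically
identical to the through-origin PIC slope, and serves as the independent
cross-check in the test suite.

Tip-level regressions of mean log relative abundance on genome size (per
body site, and within genera after genus-centering) are ordinary polynomial
least squares; significance is reported for the linear coefficient.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phylo_io import AnnotatedTree

__all__ = [
    "ContrastSet",
    "RegressionResult",
    "pic",
    "pic_pair",
    "pic_regression",
    "pic_regression_oracle_gls",
    "mean_log_abundance",
    "abundance_size_regression",
    "within_genus_regression",
]


@dataclasses.dataclass(frozen=True)
class ContrastSet:
    """Standardized contrasts, one per (resolved) internal node.

    Contrasts are emitted in post-order; polytomies are resolved into
    zero-length caterpillars deterministically (children taken in order of
    their smallest tip label), so the set is reproducible and has exactly
    n − 1 entries for an n-tip tree.
    """

    node_ids: tuple[str, ...]
    contrasts: np.ndarray  # standardized: raw difference / sqrt(variance)
    variances: np.ndarray  # expected variance (branch-length units)

    def __len__(self) -> int:
        return len(self.node_ids)


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    coefficients: dict[str, float]
    r_squared: float
    p_linear: float
    n: int
    degree: int

    @property
    def slope(self) -> float:
        return self.coefficients["linear"]


def _as_tree(tree: AnnotatedTree | dendropy.Tree) -> dendropy.Tree:
    return tree.tree if isinstance(tree, AnnotatedTree) else tree


def pic(tree: AnnotatedTree | dendropy.Tree, trait: Mapping[str, float]) -> ContrastSet:
    """Felsenstein pruning: standardized contrasts for one trait.

    At a node joining subtrees with nodal values x1, x2 and adjusted branch
    lengths v1, v2 the contrast is (x1 − x2)/√(v1 + v2), the nodal value is
    the variance-weighted mean, and the node's own branch is lengthened by
    v1·v2/(v1 + v2).  Sign convention: first minus second child in tip-label
    order.  A node where both adjusted lengths are zero is uninformative and
    raises ValueError.
    """
    tree = _as_tree(tree)
    pre_index = {id(node): i for i, node in enumerate(tree.preorder_node_iter())}
    # per node: (nodal value, adjusted edge length, smallest tip label)
    state: dict[int, tuple[float, float, str]] = {}
    node_ids: list[str] = []
    contrasts: list[float] = []
    variances: list[float] = []

    for node in tree.postorder_node_iter():
        edge_len = node.edge.length if node.edge.length is not None else 0.0
        if node.is_leaf():
            label = node.taxon.label
            if label not in trait:
                raise ValueError(f"trait value missing for tip {label!r}")
            state[id(node)] = (float(trait[label]), edge_len, label)
            continue
        items = sorted((state[id(c)] for c in node.child_nodes()), key=lambda s: s[2])
        x1, v1, lab1 = items[0]
        for j, (x2, v2, lab2) in enumerate(items[1:]):
            var = v1 + v2
            if var <= 0.0:
                raise ValueError(
                    f"uninformative contrast at node {pre_index[id(node)]}: "
                    "both adjusted branch lengths are zero"
                )
            node_ids.append(
                f"n{pre_index[id(node)]}" if j == len(items) - 2 else f"n{pre_index[id(node)]}.{j}"
            )
            contrasts.append((x1 - x2) / math.sqrt(var))
            variances.append(var)
            # weighted nodal value; a zero-length child gets infinite weight
            if v1 == 0.0:
                pass  # x1 unchanged
            elif v2 == 0.0:
                x1 = x2
            else:
                x1 = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
            v1 = v1 * v2 / var  # extra variance passed up the caterpillar
            lab1 = min(lab1, lab2)
        state[id(node)] = (x1, edge_len + v1, lab1)

    return ContrastSet(tuple(node_ids), np.asarray(contrasts), np.asarray(variances))


def pic_pair(
    tree: AnnotatedTree | dendropy.Tree,
    trait_x: Mapping[str, float],
    trait_y: Mapping[str, float],
) -> tuple[ContrastSet, ContrastSet]:
    """Contrasts for two traits on the same tree, aligned node-for-node."""
    cx = pic(tree, trait_x)
    cy = pic(tree, trait_y)
    assert cx.node_ids == cy.node_ids
    return cx, cy


def pic_regression(
    contrasts_x: ContrastSet | Sequence[float],
    contrasts_y: ContrastSet | Sequence[float],
) -> RegressionResult:
    """Least-squares regression of y-contrasts on x-contrasts through the origin.

    Through-origin is the standard model for contrasts (their expectation is
    zero under BM); R² is the uncentered coefficient and the p-value is the
    t-test on the slope with n − 1 residual degrees of freedom.
    """
    x = np.asarray(contrasts_x.contrasts if isinstance(contrasts_x, ContrastSet) else contrasts_x)
    y = np.asarray(contrasts_y.contrasts if isinstance(contrasts_y, ContrastSet) else contrasts_y)
    if x.shape != y.shape:
        raise ValueError("contrast vectors differ in length")
    if len(x) < 2:
        raise ValueError("need at least 2 contrasts for a through-origin regression")
    fit = sm.OLS(y, x[:, None]).fit()
    return RegressionResult(
        coefficients={"linear": float(fit.params[0])},
        r_squared=float(fit.rsquared),
        p_linear=float(fit.pvalues[0]),
        n=len(x),
        degree=1,
    )


def _bm_covariance(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """C_ij = root-to-MRCA path length (C_ii = tip depth)."""
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[id(parent)] + (node.edge.length or 0.0)
        depth[id(node)] = d
    C = np.zeros((n, n))
    leafsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            leafsets[id(node)] = [i]
            C[i, i] = depth[id(node)]
            continue
        children = [leafsets[id(c)] for c in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        C[i, j] = C[j, i] = d
        leafsets[id(node)] = [i for ch in children for i in ch]
    return C


def pic_regression_oracle_gls(
    tree: AnnotatedTree | dendropy.Tree,
    trait_x: Mapping[str, float],
    trait_y: Mapping[str, float],
) -> float:
    """Independent slope oracle: BM generalized least squares on tip values.

    Fits y = a + b·x under covariance C_ij = shared path length; the
    intercept absorbs the phylogenetic mean, making the GLS slope b
    algebraically equal to the through-origin PIC regression slope.  Intended
    for small trees (dense O(n³) solve).
    """
    tree = _as_tree(tree)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    x = np.array([trait_x[l] for l in labels])
    y = np.array([trait_y[l] for l in labels])
    C = _bm_covariance(tree, labels)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular BM covariance matrix") from exc
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ Cinv @ X, X.T @ Cinv @ y)
    return float(beta[1])


# ---------------------------------------------------------------------------
# Tip-level abundance regressions


def mean_log_abundance(
    abundance: pd.DataFrame,
    habitat: str,
    zero_policy: str = "drop",
) -> pd.Series:
    """Per-species mean over hosts of log10 relative abundance in one habitat.

    ``zero_policy='drop'`` discards zero abundances before the log;
    ``'half_min'`` imputes half the smallest nonzero abundance in the
    habitat, keeping absent observations in the mean.
    """
    sub = abundance[abundance["habitat"] == habitat].copy()
    if zero_policy == "drop":
        sub = sub[sub["rel_abundance"] > 0]
    elif zero_policy == "half_min":
        nonzero = sub.loc[sub["rel_abundance"] > 0, "rel_abundance"]
        if nonzero.empty:
            raise ValueError(f"no nonzero abundances in habitat {habitat!r}")
        floor = nonzero.min() / 2.0
        sub.loc[sub["rel_abundance"] <= 0, "rel_abundance"] = floor
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if sub.empty:
        raise ValueError(f"no abundance observations in habitat {habitat!r}")
    return np.log10(sub.set_index("species")["rel_abundance"]).groupby(level=0).mean()


def _poly_fit(x: np.ndarray, y: np.ndarray, degree: int) -> RegressionResult:
    cols = {"intercept": np.ones_like(x), "linear": x}
    if degree == 2:
        cols["quadratic"] = x * x
    elif degree != 1:
        raise ValueError("degree must be 1 or 2")
    X = pd.DataFrame(cols)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        coefficients={k: float(v) for k, v in fit.params.items()},
        r_squared=float(fit.rsquared),
        p_linear=float(fit.pvalues["linear"]),
        n=len(x),
        degree=degree,
    )


def abundance_size_regression(
    abundance: pd.DataFrame,
    sizes_mb: Mapping[str, float],
    habitat: str,
    degree: int = 2,
    zero_policy: str = "drop",
) -> RegressionResult:
    """Polynomial OLS of mean log10 relative abundance on genome size (Mb).

    One point per species detected in the habitat; significance is the
    t-test on the linear coefficient (the quadratic term, when fitted,
    captures curvature without changing the question asked of the slope).
    """
    y_by_species = mean_log_abundance(abundance, habitat, zero_policy)
    species = [s for s in y_by_species.index if s in sizes_mb]
    if len(species) < degree + 2:
        raise ValueError(
            f"habitat {habitat!r}: {len(species)} species with sizes, "
            f"need at least {degree + 2} for degree {degree}"
        )
    x = np.array([sizes_mb[s] for s in species], dtype=float)
    y = y_by_species.loc[species].to_numpy(dtype=float)
    return _poly_fit(x, y, degree)


def within_genus_regression(
    sizes_mb: Mapping[str, float],
    values: Mapping[str, float],
    genera: Mapping[str, str],
) -> RegressionResult:
    """Pooled within-genus regression via genus-centering.

    Both variables are centered on their genus means (genera with a single
    species carry no within-genus information and are dropped), removing
    between-genus variation so the slope reflects only divergence among
    congeners.
    """
    df = pd.DataFrame(
        {
            "x": pd.Series(dict(sizes_mb)),
            "y": pd.Series(dict(values)),
            "genus": pd.Series(dict(genera)),
        }
    ).dropna()
    counts = df.groupby("genus")["x"].transform("size")
    df = df[counts >= 2]
    if df.empty:
        raise ValueError("no genus contains at least 2 species")
    df["xc"] = df["x"] - df.groupby("genus")["x"].transform("mean")
    df["yc"] = df["y"] - df.groupby("genus")["y"].transform("mean")
    return _poly_fit(df["xc"].to_numpy(), df["yc"].to_numpy(), degree=1)
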