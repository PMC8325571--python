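"""Synthetic study cohorts with known ground truth.

The generator emulates the structure of a body-site isolate-genome survey:
an ultrametric pure-birth (Yule) phylogeny, body-site residency switching
along branches as a continuous-time Markov chain, and log genome size
evolving as Brownian motion with a habitat-dependent deterministic trend
("trend-BM") — while a lineage resides in the gut its expected log size
drifts upward at ``gut_trend_delta`` per unit branch length.  An
observation model turns true sizes into (assembly size, completeness)
pairs exactly invertible by the completeness correction; genera and
species are defined by cutting the ultrametric tree at fixed ages; and
companion abundance, MAG and annotation-enrichment tables are generated
with simple parametric models whose ground-truth coefficients are recorded
in the manifest, so every pipeline stage has a recoverable target.

All stages draw from named substreams of one master seed, so a full cohort
is bit-reproducible and single stages can be replayed in isolation.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from ._rng import stage_rng
from .phylo_io import (
    AnnotatedTree,
    Habitat,
    TipRecord,
    join_tree_metadata,
    tree_from_string,
    write_newick,
)

__all__ = [
    "AbundanceParams",
    "MagParams",
    "EnrichmentParams",
    "SimulationConfig",
    "Cohort",
    "simulate_tree",
    "simulate_habitats",
    "simulate_genome_sizes",
    "apply_observation_model",
    "assign_clades",
    "simulate_cohort",
    "simulate_abundance_table",
    "write_cohort",
]

HABITATS: tuple[str, ...] = ("gut", "oral", "urogenital", "skin", "airways")


@dataclasses.dataclass
class AbundanceParams:
    """Per-habitat generative model: mean log10 relative abundance of a
    species is ``intercept + slope_per_mb·size_Mb`` plus species noise, with
    additional per-host scatter."""

    intercept: float = -5.0
    slope_per_mb: float = 1.0
    noise_sd: float = 0.6
    host_sd: float = 0.3


@dataclasses.dataclass
class MagParams:
    extra_site_prob: float = 0.35
    mags_per_presence: tuple[int, int] = (1, 4)
    completeness_range: tuple[float, float] = (80.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 8.0)
    gut_logsize_shift: float = 0.014
    size_noise_sd: float = 0.01


@dataclasses.dataclass
class EnrichmentParams:
    n_annotations: dict[str, int] = dataclasses.field(
        default_factory=lambda: {
            "prodigal_cluster": 600,
            "COG": 300,
            "Pfam": 300,
            "TIGRFAM": 150,
            "KEGG_module": 120,
            "KEGG_class": 40,
        }
    )
    zero_fraction: float = 0.45
    p_gut_positive: float = 0.65
    crispr_rate_zero: float = 0.001
    crispr_rate_nonzero: float = 0.005


def _default_abundance() -> dict[str, AbundanceParams]:
    # Positive size–abundance slope in the gut, negative elsewhere.
    out = {"gut": AbundanceParams(intercept=-5.0, slope_per_mb=1.0)}
    for h in ("oral", "urogenital", "skin", "airways"):
        out[h] = AbundanceParams(intercept=-3.0, slope_per_mb=-1.0)
    return out


@dataclasses.dataclass
class SimulationConfig:
    """Every generative parameter of a synthetic cohort.

    Defaults define the reference study conditions: a cohort of ~2,000
    isolate genomes (the scale of the real body-site surveys this emulates),
    moderate habitat switching so that each cohort yields on the order of a
    hundred phylogenetically independent comparisons, log-size BM noise
    giving a realistic 2–5 Mb genome-size spread, a gut expansion trend
    producing single-digit-percent mean size differences, and completeness
    in the high-quality (90–100%) band.
    """

    n_tips: int = 2048
    birth_rate: float = 1.0
    switch_rate: float = 0.12  # uniform off-diagonal CTMC rate between sites
    root_habitat: str = "oral"
    root_log_size: float = math.log(3_000_000.0)
    bm_sigma2: float = 0.02
    gut_trend_delta: float = 0.1
    nongut_trend_delta: float = 0.0
    shift_at_transition: bool = False  # point shift on entering the gut instead of drift
    completeness_range: tuple[float, float] = (90.0, 100.0)
    genus_depth: float = 1.2
    species_depth: float = 0.4
    pathogen_fraction: float = 0.05
    n_hosts: int = 10
    abundance: dict[str, AbundanceParams] = dataclasses.field(default_factory=_default_abundance)
    mag: MagParams = dataclasses.field(default_factory=MagParams)
    enrichment: EnrichmentParams = dataclasses.field(default_factory=EnrichmentParams)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_tips < 2:
            problems.append("n_tips must be >= 2")
        if self.birth_rate <= 0:
            problems.append("birth_rate must be > 0")
        if self.switch_rate < 0:
            problems.append("switch_rate must be >= 0")
        if self.bm_sigma2 < 0:
            problems.append("bm_sigma2 must be >= 0")
        lo, hi = self.completeness_range
        if not (0.0 < lo <= hi <= 100.0):
            problems.append("completeness_range must be within (0, 100] with lo <= hi")
        if self.root_habitat not in HABITATS:
            problems.append(f"root_habitat must be one of {HABITATS}")
        if not (0.0 <= self.pathogen_fraction <= 1.0):
            problems.append("pathogen_fraction must lie in [0, 1]")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    def rate_matrix(self) -> np.ndarray:
        k = len(HABITATS)
        Q = np.full((k, k), self.switch_rate)
        np.fill_diagonal(Q, -(k - 1) * self.switch_rate)
        return Q

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "abundance" in data:
            data["abundance"] = {
                h: AbundanceParams(**p) if isinstance(p, Mapping) else p
                for h, p in data["abundance"].items()
            }
        if isinstance(data.get("mag"), Mapping):
            mag = dict(data["mag"])
            if "mags_per_presence" in mag:
                mag["mags_per_presence"] = tuple(mag["mags_per_presence"])
            if "completeness_range" in mag:
                mag["completeness_range"] = tuple(mag["completeness_range"])
            if "contamination_range" in mag:
                mag["contamination_range"] = tuple(mag["contamination_range"])
            data["mag"] = MagParams(**mag)
        if isinstance(data.get("enrichment"), Mapping):
            data["enrichment"] = EnrichmentParams(**data["enrichment"])
        if "completeness_range" in data:
            data["completeness_range"] = tuple(data["completeness_range"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Tree


def _rng_for(seed_or_rng: int | np.random.Generator, stage: str) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return stage_rng(int(seed_or_rng), stage)


def simulate_tree(
    n_tips: int, birth_rate: float, seed: int | np.random.Generator
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree with labelled tips.

    Starts from the root's two daughter lineages; with k lineages alive the
    next split arrives after Exp(k·birth_rate) and hits a uniformly chosen
    lineage.  After the n-th lineage appears, one further Exp(n·birth_rate)
    interval runs to the present, so all tips end at the same depth.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = _rng_for(seed, "tree")
    # node: [start_time, end_time, left, right]; leaves have no children
    root_children = [[0.0, None, None, None], [0.0, None, None, None]]
    active = list(root_children)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node = active.pop(i)
        node[1] = t
        node[2] = [t, None, None, None]
        node[3] = [t, None, None, None]
        active.extend((node[2], node[3]))
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for node in active:
        node[1] = t

    counter = [0]
    parts = []

    def render(node) -> str:
        length = node[1] - node[0]
        if node[2] is None:
            counter[0] += 1
            return f"t{counter[0]:04d}:{length:.12g}"
        return f"({render(node[2])},{render(node[3])}):{length:.12g}"

    newick = f"({render(root_children[0])},{render(root_children[1])});"
    del parts
    return tree_from_string(newick)


# ---------------------------------------------------------------------------
# Habitat history


@dataclasses.dataclass
class HabitatSimulation:
    """Tip states plus the full state path along every branch.

    ``paths`` is keyed by the pre-order index of the branch's child node and
    holds ``(state, duration)`` segments from the parent end of the branch.
    """

    tip_habitats: dict[str, Habitat]
    paths: dict[int, list[tuple[str, float]]]
    states: tuple[str, ...] = HABITATS


def simulate_habitats(
    tree: dendropy.Tree,
    rate_matrix: np.ndarray,
    root_habitat: str,
    seed: int | np.random.Generator,
    states: Sequence[str] = HABITATS,
) -> HabitatSimulation:
    """Continuous-time Markov simulation of body-site residency."""
    Q = np.asarray(rate_matrix, dtype=float)
    k = len(states)
    if Q.shape != (k, k):
        raise ValueError("rate matrix shape does not match the state list")
    if (Q[~np.eye(k, dtype=bool)] < 0).any():
        raise ValueError("off-diagonal rates must be nonnegative")
    rng = _rng_for(seed, "habitats")
    state_index = {s: i for i, s in enumerate(states)}
    root_state = state_index[root_habitat]

    node_state: dict[int, int] = {}
    paths: dict[int, list[tuple[str, float]]] = {}
    tip_habitats: dict[str, Habitat] = {}
    for idx, node in enumerate(tree.preorder_node_iter()):
        parent = node.parent_node
        if parent is None:
            node_state[id(node)] = root_state
            continue
        s = node_state[id(parent)]
        remaining = node.edge.length or 0.0
        segments: list[tuple[str, float]] = []
        while True:
            out_rate = -Q[s, s]
            if out_rate <= 0.0:
                segments.append((states[s], remaining))
                break
            dwell = rng.exponential(1.0 / out_rate)
            if dwell >= remaining:
                segments.append((states[s], remaining))
                break
            segments.append((states[s], dwell))
            remaining -= dwell
            probs = Q[s].clip(min=0.0)
            probs[s] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
        node_state[id(node)] = s
        paths[idx] = segments
        if node.is_leaf():
            tip_habitats[node.taxon.label] = Habitat(states[s])
    return HabitatSimulation(tip_habitats=tip_habitats, paths=paths, states=tuple(states))


# ---------------------------------------------------------------------------
# Genome sizes


@dataclasses.dataclass
class SizeSimulation:
    log_sizes: dict[str, float]
    true_sizes: dict[str, int]
    gut_dwell: dict[str, float]


def simulate_genome_sizes(
    tree: dendropy.Tree,
    habitat_sim: HabitatSimulation,
    bm_sigma2: float,
    gut_trend_delta: float,
    root_log_size: float,
    seed: int | np.random.Generator,
    nongut_trend_delta: float = 0.0,
    shift_at_transition: bool = False,
) -> SizeSimulation:
    """Trend-BM evolution of log genome size along the habitat history.

    Along each branch, log size gains a deterministic trend — by default
    ``gut_trend_delta`` per unit time spent in the gut (and
    ``nongut_trend_delta`` per unit time elsewhere) — plus a Brownian
    increment of variance ``bm_sigma2 × branch length``.  With
    ``shift_at_transition`` the trend is replaced by a point shift of
    ``gut_trend_delta`` at each transition into the gut (and
    ``nongut_trend_delta`` at each transition out).
    """
    rng = _rng_for(seed, "sizes")
    log_val: dict[int, float] = {}
    gut_time: dict[int, float] = {}
    out = SizeSimulation({}, {}, {})
    for idx, node in enumerate(tree.preorder_node_iter()):
        parent = node.parent_node
        if parent is None:
            log_val[id(node)] = root_log_size
            gut_time[id(node)] = 0.0
            continue
        segments = habitat_sim.paths[idx]
        length = node.edge.length or 0.0
        edge_gut = sum(d for s, d in segments if s == "gut")
        if shift_at_transition:
            trend = 0.0
            prev = None
            for s, _ in segments:
                if prev is not None and s != prev:
                    trend += gut_trend_delta if s == "gut" else nongut_trend_delta
                prev = s
        else:
            trend = gut_trend_delta * edge_gut + nongut_trend_delta * (length - edge_gut)
        noise = rng.standard_normal() * math.sqrt(bm_sigma2 * length) if length > 0 else 0.0
        log_val[id(node)] = log_val[id(parent)] + trend + noise
        gut_time[id(node)] = gut_time[id(parent)] + edge_gut
        if node.is_leaf():
            label = node.taxon.label
            out.log_sizes[label] = log_val[id(node)]
            out.true_sizes[label] = max(1, round(math.exp(log_val[id(node)])))
            out.gut_dwell[label] = gut_time[id(node)]
    return out


def apply_observation_model(
    true_sizes: Mapping[str, int],
    completeness_range: tuple[float, float],
    seed: int | np.random.Generator,
) -> dict[str, tuple[int, float]]:
    """Draw completeness ~ Uniform(lo, hi) and the implied assembly size.

    assembly = round(true × completeness/100), so the completeness
    correction recovers the true size to within rounding (±1 bp).
    """
    lo, hi = completeness_range
    if not (0.0 < lo <= hi <= 100.0):
        raise ValueError("completeness_range must be within (0, 100]")
    rng = _rng_for(seed, "observation")
    out: dict[str, tuple[int, float]] = {}
    for tip in sorted(true_sizes):
        c = float(rng.uniform(lo, hi))
        out[tip] = (max(1, round(true_sizes[tip] * c / 100.0)), c)
    return out


# ---------------------------------------------------------------------------
# Taxonomy by tree slicing


def assign_clades(tree: dendropy.Tree, cut_age: float, prefix: str) -> dict[str, str]:
    """Label tips by the clade their lineage belongs to at ``cut_age``
    before the present: every edge crossing that time slice roots one clade.
    A convenience taxonomy for ultrametric simulated trees."""
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = (0.0 if parent is None else depth[id(parent)] + (node.edge.length or 0.0))
    total = max(depth[id(l)] for l in tree.leaf_node_iter())
    labels: dict[str, str] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        age = total - depth[id(node)]
        parent_age = math.inf if parent is None else total - depth[id(parent)]
        if age <= cut_age < parent_age:
            counter += 1
            name = f"{prefix}{counter:03d}"
            for leaf in node.leaf_iter():
                labels[leaf.taxon.label] = name
    return labels


# ---------------------------------------------------------------------------
# Abundance


def simulate_abundance_table(
    sizes_mb: Mapping[str, float],
    habitat: str,
    params: AbundanceParams,
    n_hosts: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Species × host relative abundances for one habitat.

    Per-species mean log10 abundance follows the linear size model; hosts
    add independent scatter.  Each host's abundances are rescaled to sum to
    at most 1 — a common multiplicative factor per host, which shifts every
    species' log abundance equally and therefore leaves the generative
    slope untouched.
    """
    species = sorted(sizes_mb)
    mu = {
        s: params.intercept
        + params.slope_per_mb * sizes_mb[s]
        + rng.normal(0.0, params.noise_sd)
        for s in species
    }
    rows = []
    for j in range(n_hosts):
        host = f"h{j:03d}"
        # a relative abundance cannot exceed 1: cap the log10 value at 0
        vals = np.array(
            [10.0 ** min(mu[s] + rng.normal(0.0, params.host_sd), 0.0) for s in species]
        )
        total = vals.sum()
        if total > 0.99:
            vals = vals * (0.99 / total)
        for s, v in zip(species, vals):
            rows.append({"species": s, "habitat": habitat, "host_id": host, "rel_abundance": v})
    return pd.DataFrame(rows, columns=["species", "habitat", "host_id", "rel_abundance"])


# ---------------------------------------------------------------------------
# Full cohort


@dataclasses.dataclass
class Cohort:
    config: SimulationConfig
    atree: AnnotatedTree
    records: dict[str, TipRecord]
    truth: pd.DataFrame
    abundance: pd.DataFrame
    mags: pd.DataFrame
    enrichment: pd.DataFrame
    manifest: dict

    @property
    def tree(self) -> dendropy.Tree:
        return self.atree.tree


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """End-to-end generation of one synthetic study cohort."""
    config.validate()
    seed = config.seed
    tree = simulate_tree(config.n_tips, config.birth_rate, stage_rng(seed, "tree"))
    habitat_sim = simulate_habitats(
        tree, config.rate_matrix(), config.root_habitat, stage_rng(seed, "habitats")
    )
    size_sim = simulate_genome_sizes(
        tree,
        habitat_sim,
        config.bm_sigma2,
        config.gut_trend_delta,
        config.root_log_size,
        stage_rng(seed, "sizes"),
        nongut_trend_delta=config.nongut_trend_delta,
        shift_at_transition=config.shift_at_transition,
    )
    observed = apply_observation_model(
        size_sim.true_sizes, config.completeness_range, stage_rng(seed, "observation")
    )
    genera = assign_clades(tree, config.genus_depth, "G")
    species = assign_clades(tree, config.species_depth, "S")

    rng_path = stage_rng(seed, "pathogen")
    flagged = {
        sp for sp in sorted(set(species.values())) if rng_path.random() < config.pathogen_fraction
    }

    records: dict[str, TipRecord] = {}
    truth_rows = []
    for leaf in tree.leaf_node_iter():
        tip = leaf.taxon.label
        assembly, completeness = observed[tip]
        records[tip] = TipRecord(
            tip_id=tip,
            genus=genera[tip],
            species=species[tip],
            habitat=habitat_sim.tip_habitats[tip],
            assembly_size=assembly,
            completeness=completeness,
            pathogen_flag=species[tip] in flagged,
        )
        truth_rows.append(
            {
                "tip_id": tip,
                "genus": genera[tip],
                "species": species[tip],
                "habitat": habitat_sim.tip_habitats[tip].value,
                "true_size": size_sim.true_sizes[tip],
                "log_size": size_sim.log_sizes[tip],
                "gut_dwell": size_sim.gut_dwell[tip],
                "assembly_size": assembly,
                "completeness": completeness,
                "pathogen_flag": species[tip] in flagged,
            }
        )
    truth = pd.DataFrame(truth_rows)
    atree = join_tree_metadata(tree, records)

    # Species-level summaries feeding abundance and MAG tables.
    sp_group = truth.groupby("species")
    sp_size_mb = (sp_group["true_size"].mean() / 1e6).to_dict()
    sp_habitats = truth.groupby("species")["habitat"].agg(lambda s: sorted(set(s))).to_dict()

    rng_ab = stage_rng(seed, "abundance")
    frames = []
    for habitat in HABITATS:
        present = {s: sp_size_mb[s] for s, habs in sorted(sp_habitats.items()) if habitat in habs}
        if len(present) < 2:
            continue
        frames.append(
            simulate_abundance_table(
                present, habitat, config.abundance[habitat], config.n_hosts, rng_ab
            )
        )
    abundance = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["species", "habitat", "host_id", "rel_abundance"])
    )

    rng_mag = stage_rng(seed, "mags")
    mp = config.mag
    mag_rows = []
    for sp in sorted(sp_habitats):
        presences = list(sp_habitats[sp])
        if rng_mag.random() < mp.extra_site_prob:
            extra = str(rng_mag.choice([h for h in HABITATS if h not in presences] or presences))
            if extra not in presences:
                presences.append(extra)
        for habitat in presences:
            n_mags = int(rng_mag.integers(mp.mags_per_presence[0], mp.mags_per_presence[1] + 1))
            for i in range(n_mags):
                comp = float(rng_mag.uniform(*mp.completeness_range))
                contam = float(rng_mag.uniform(*mp.contamination_range))
                shift = mp.gut_logsize_shift if habitat == "gut" else 0.0
                base = sp_size_mb[sp] * 1e6 * math.exp(shift + rng_mag.normal(0, mp.size_noise_sd))
                mag_rows.append(
                    {
                        "bin_id": f"{sp}_{habitat}_{i}",
                        "species_bin": sp,
                        "habitat": habitat,
                        "completeness": comp,
                        "contamination": contam,
                        "genome_size": max(1, round(base * comp / 100.0)),
                    }
                )
    mags = pd.DataFrame(
        mag_rows,
        columns=["bin_id", "species_bin", "habitat", "completeness", "contamination", "genome_size"],
    )

    rng_enr = stage_rng(seed, "enrichment")
    ep = config.enrichment
    enr_rows = []
    for source in sorted(ep.n_annotations):
        for i in range(ep.n_annotations[source]):
            if rng_enr.random() < ep.zero_fraction:
                score = 0.0
                crispr = rng_enr.random() < ep.crispr_rate_zero
            else:
                magnitude = float(rng_enr.exponential(1.0))
                sign = 1.0 if rng_enr.random() < ep.p_gut_positive else -1.0
                score = sign * magnitude
                crispr = rng_enr.random() < ep.crispr_rate_nonzero
            enr_rows.append(
                {
                    "annotation_id": f"{source}_{i:05d}",
                    "source": source,
                    "score": score,
                    "category_flags": "CRISPR" if crispr else "",
                }
            )
    enrichment = pd.DataFrame(
        enr_rows, columns=["annotation_id", "source", "score", "category_flags"]
    )

    manifest = {
        "config": config.to_dict(),
        "seed": seed,
        "n_comparable_genera": int(truth.groupby("genus")["habitat"].nunique().gt(1).sum()),
        "ground_truth": {
            "gut_trend_delta": config.gut_trend_delta,
            "abundance_slopes": {h: config.abundance[h].slope_per_mb for h in config.abundance},
            "mag_gut_logsize_shift": mp.gut_logsize_shift,
        },
    }
    return Cohort(
        config=config,
        atree=atree,
        records=records,
        truth=truth,
        abundance=abundance,
        mags=mags,
        enrichment=enrichment,
        manifest=manifest,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write the cohort in the exact formats the readers consume."""
    from .phylo_io import write_results

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_newick(cohort.tree, out / "tree.nwk")
    tips = pd.DataFrame(
        [
            {
                "tip_id": r.tip_id,
                "genus": r.genus,
                "species": r.species,
                "habitat": r.habitat.value,
                "assembly_size": r.assembly_size,
                "completeness": r.completeness,
                "pathogen_flag": str(r.pathogen_flag).lower(),
            }
            for r in (cohort.records[t] for t in sorted(cohort.records))
        ]
    )
    write_results(
        {
            "tips": tips,
            "truth": cohort.truth,
            "abundance": cohort.abundance,
            "mags": cohort.mags,
            "enrichment": cohort.enrichment,
        },
        out,
        manifest=cohort.manifest,
        timestamp=False,
    )
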