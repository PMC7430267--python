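"""Synthetic datasets with planted isolation-by-distance structure.

The generator produces an aligned haplotype matrix plus sample metadata
whose expected pairwise sequence divergence follows a linear
genetic-vs-geographic relationship ``E[d] = a + b * km``, so that the
estimators in :mod:`mitoibd.ibd_analysis` can be tested against known
truth.  Two genealogy constructions are available:

``transect-path`` (default)
    Populations sit on a one-dimensional transect and sequences evolve
    along the transect path, each inter-population segment contributing
    ``b * Δkm`` expected substitutions/site (times multiplicative
    log-normal noise) and each tip a private ``a / 2``.  Because
    geographic distances on a line are additive, every population pair
    satisfies the linear expectation exactly, which keeps slope-recovery
    tests sharp.

``upgma``
    An ultrametric genealogy from average-linkage clustering of the
    geographic distance matrix, with node heights scaled so two
    populations whose clusters merge at geographic distance h diverge by
    ``a + b * h`` in expectation.  The expectation is exact per cluster
    pair, not per population pair, which attenuates regression slopes;
    it is retained for generating nested clade structure.

Sequences evolve under the Kimura two-parameter model with
transition/transversion ratio kappa, using the closed-form branch
transition probabilities (branch lengths are exact in expectation).
Optional extras: a deep split adding extra divergence between two clade
groups, and a planted introduction (a source haplotype copied to a
distant locality) with the ground truth recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .alignio import Alignment, SampleTable, write_alignment, write_sample_table
from .distances import DistanceMatrix, geographic_distance_matrix

__all__ = [
    "TreeNode",
    "SimConfig",
    "SimTruth",
    "DeepSplit",
    "PlantedIntroduction",
    "transect_coordinates",
    "build_geo_genealogy",
    "build_transect_genealogy",
    "evolve_sequences",
    "simulate_ibd_dataset",
    "write_dataset",
]

KM_PER_DEGREE_LAT = 111.1950802335329  # pi * 6371.0088 / 180


@dataclass
class TreeNode:
    """Rooted tree with branch lengths in expected substitutions/site."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    height: float = 0.0  # root-to-leaf distance below this node (ultrametric trees)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def branch_lengths(self) -> list[float]:
        out = []
        for child, bl in self.children:
            out.append(bl)
            out.extend(child.branch_lengths())
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label or ""
            inner = ",".join(f"{fmt(c)}:{bl:.10g}" for c, bl in node.children)
            return f"({inner})"

        return fmt(self) + ";"


def _lognormal_factor(rng: np.random.Generator, sigma: float, size=None):
    """Multiplicative noise with mean 1 (log-normal, log-sd sigma)."""
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def build_geo_genealogy(
    geographic: DistanceMatrix,
    b: float,
    a: float = 0.0,
    noise: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> TreeNode:
    """Ultrametric genealogy from average-linkage clustering of geography.

    Two populations whose clusters merge at geographic distance h have
    expected divergence ``a + b * h``; node heights get multiplicative
    log-normal noise and are made non-decreasing toward the root.
    """
    if a < 0:
        raise ValueError("negative intercept implies negative node heights")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = geographic.n
    if n == 1:
        return TreeNode(label=geographic.labels[0])
    if n < 1:
        raise ValueError("need at least 1 population")
    Z = linkage(squareform(geographic.values, checks=False), method="average")
    nodes = [TreeNode(label=lab) for lab in geographic.labels]
    for left, right, geo_h, _ in Z:
        lnode, rnode = nodes[int(left)], nodes[int(right)]
        height = 0.5 * (a + b * geo_h) * _lognormal_factor(rng, noise)
        height = max(height, lnode.height, rnode.height)
        parent = TreeNode(
            children=[(lnode, height - lnode.height), (rnode, height - rnode.height)],
            height=height,
        )
        nodes.append(parent)
    return nodes[-1]


def build_transect_genealogy(
    labels: Sequence[str],
    positions_km: Sequence[float],
    b: float,
    a: float = 0.0,
    noise: float = 0.0,
    seed: int | np.random.Generator | None = None,
    extra_divergence_after: int | None = None,
    extra_divergence: float = 0.0,
) -> TreeNode:
    """Path genealogy along a 1-D transect with exact linear expectation.

    ``extra_divergence_after=k`` inserts ``extra_divergence`` expected
    substitutions/site into the segment between populations k-1 and k
    (0-based), creating a deep split between the two sides.
    """
    if a < 0:
        raise ValueError("negative intercept implies negative branch lengths")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = np.argsort(positions_km, kind="stable")
    labs = [labels[i] for i in order]
    pos = np.asarray(positions_km, dtype=float)[order]
    tips = [TreeNode(label=lab) for lab in labs]

    def tip_edge(k: int) -> tuple[TreeNode, float]:
        return tips[k], a / 2.0

    # backbone built right-to-left; each backbone node holds a tip and the next segment
    node = TreeNode(children=[tip_edge(len(labs) - 1)])
    for k in range(len(labs) - 2, -1, -1):
        seg = b * (pos[k + 1] - pos[k]) * _lognormal_factor(rng, noise)
        if extra_divergence_after is not None and k + 1 == extra_divergence_after:
            seg += extra_divergence
        node = TreeNode(children=[tip_edge(k), (node, seg)])
    return node


def _k80_branch_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after branch length t."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta  # alpha + 2*beta == 1: t is in expected subs/site
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    return p_same, p_ts, p_tv


def evolve_sequences(
    tree: TreeNode,
    L: int = 784,
    kappa: float = 4.0,
    seed: int | np.random.Generator | None = None,
) -> Alignment:
    """Evolve sequences down a tree under K80 and return the leaf alignment.

    The root sequence is uniform over A/C/G/T; each branch applies the
    exact K80 transition probabilities for its length, independently per
    site.  Leaf order follows tree traversal order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=L, dtype=np.uint8)
    ids: list[str] = []
    rows: list[np.ndarray] = []

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        if node.is_leaf:
            ids.append(node.label or f"leaf{len(ids) + 1}")
            rows.append(seq)
            return
        for child, bl in node.children:
            if bl == 0:
                walk(child, seq)
                continue
            p_same, p_ts, p_tv = _k80_branch_probs(bl, kappa)
            draw = rng.choice(4, size=L, p=[p_same, p_ts, p_tv, p_tv])
            # 0: unchanged; 1: transition partner; 2/3: the two transversions
            child_seq = seq.copy()
            child_seq[draw == 1] ^= 2
            child_seq[draw == 2] ^= 1
            child_seq[draw == 3] ^= 3
            walk(child, child_seq)

    walk(tree, root_seq)
    bases = np.array(list("ACGT"), dtype="<U1")
    return Alignment(ids, bases[np.vstack(rows)] if rows else np.empty((0, 0), "<U1"))


@dataclass(frozen=True)
class DeepSplit:
    """Extra divergence between the first ``n_left`` populations and the rest."""

    n_left: int
    extra_divergence: float  # expected substitutions/site added between the groups
    labels: tuple[str, str] = ("A", "B")


@dataclass(frozen=True)
class PlantedIntroduction:
    """Copy the source population's haplotype to a distant locality.

    With ``share_with_neighbor`` (the default) the source haplotype is
    also assigned to the population adjacent to the source, emulating
    the local haplotype sharing seen in real data; this is what lets a
    purely genetic screen tell the source side from the introduced side.
    """

    source_population: str | int = 0  # label, or index along the transect
    destination_lat: float | None = None
    destination_lon: float | None = None
    offset_km: float = 200.0  # used when destination coordinates are not given
    sample_id: str = "intro1"
    share_with_neighbor: bool = True


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror the empirical setting the estimators target: a 784
    site mitochondrial fragment, transition/transversion ratio 4, ~30
    populations spread over a ~300 km region, and an IBD slope of
    2e-4 substitutions/site per km.
    """

    n_populations: int = 30
    samples_per_population: int = 1
    sequence_length: int = 784
    slope: float = 2e-4  # substitutions/site per km
    intercept: float = 0.0  # substitutions/site
    kappa: float = 4.0
    noise: float = 0.1  # log-sd of multiplicative branch noise
    transect_length_km: float = 300.0
    coordinates: list[tuple[str, float, float]] | None = None  # (label, lat, lon)
    genealogy: str = "transect-path"  # or "upgma"
    deep_split: DeepSplit | None = None
    introduction: PlantedIntroduction | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if self.sequence_length < 1:
            raise ValueError("sequence length must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.genealogy not in {"transect-path", "upgma"}:
            raise ValueError(f"unknown genealogy construction: {self.genealogy!r}")


@dataclass
class SimTruth:
    """Ground truth serialized alongside every simulated dataset."""

    slope: float
    intercept: float
    kappa: float
    noise: float
    seed: int
    clades: dict[str, str]
    introduced_ids: list[str]
    introduction_source: str | None
    branch_lengths: list[float]
    tree_newick: str
    haplotype_shared_with: str | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


def transect_coordinates(
    n: int,
    length_km: float,
    seed: int | np.random.Generator | None = None,
    *,
    base_lat: float = 33.0,
    longitude: float = -117.0,
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Random population localities along a south-north transect.

    Returns (labels, latitudes, longitudes, positions_km); positions are
    sorted so labels are ordered along the transect.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = np.sort(rng.uniform(0.0, length_km, size=n))
    labels = [f"p{k + 1:02d}" for k in range(n)]
    lats = base_lat + pos / KM_PER_DEGREE_LAT
    lons = np.full(n, longitude)
    return labels, lats, lons, pos


def simulate_ibd_dataset(config: SimConfig) -> tuple[Alignment, SampleTable, SimTruth]:
    """Generate an alignment, sample table, and ground truth from one config."""
    import pandas as pd

    ss = np.random.SeedSequence(config.seed)
    rng_coord, rng_tree, rng_seq = (np.random.default_rng(s) for s in ss.spawn(3))

    if config.coordinates is not None:
        labels = [str(lab) for lab, _, _ in config.coordinates]
        lats = np.array([la for _, la, _ in config.coordinates], dtype=float)
        lons = np.array([lo for _, _, lo in config.coordinates], dtype=float)
        pos = None
    else:
        labels, lats, lons, pos = transect_coordinates(
            config.n_populations, config.transect_length_km, rng_coord
        )

    split_at = config.deep_split.n_left if config.deep_split else None
    if config.genealogy == "transect-path" and pos is not None:
        tree = build_transect_genealogy(
            labels,
            pos,
            config.slope,
            config.intercept,
            config.noise,
            rng_tree,
            extra_divergence_after=split_at,
            extra_divergence=(
                config.deep_split.extra_divergence if config.deep_split else 0.0
            ),
        )
    else:
        geo = geographic_distance_matrix(labels, lats, lons)
        tree = build_geo_genealogy(
            geo, config.slope, config.intercept, config.noise, rng_tree
        )
        if config.deep_split is not None:
            raise ValueError("deep splits are supported on the transect genealogy only")
    pop_haplotypes = evolve_sequences(
        tree, config.sequence_length, config.kappa, rng_seq
    )
    hap = {pop: pop_haplotypes.sequence(pop) for pop in labels}

    source_pop = None
    shared_with = None
    if config.introduction is not None:
        intro = config.introduction
        source_pop = (
            labels[intro.source_population]
            if isinstance(intro.source_population, int)
            else str(intro.source_population)
        )
        if source_pop not in labels:
            raise ValueError(f"unknown source population: {source_pop!r}")
        if intro.share_with_neighbor and len(labels) > 1:
            k = labels.index(source_pop)
            shared_with = labels[k + 1] if k + 1 < len(labels) else labels[k - 1]
            hap[shared_with] = hap[source_pop]

    clades: dict[str, str] = {}
    rows = []
    ids: list[str] = []
    seqs: list[str] = []
    for k, pop in enumerate(labels):
        if config.deep_split is not None:
            clade = (
                config.deep_split.labels[0]
                if k < config.deep_split.n_left
                else config.deep_split.labels[1]
            )
        else:
            clade = "A"
        seq = hap[pop]
        n_copies = config.samples_per_population
        for c in range(n_copies):
            sid = pop if n_copies == 1 else f"{pop}{chr(ord('a') + c)}"
            ids.append(sid)
            seqs.append(seq)
            clades[sid] = clade
            rows.append(
                {
                    "sample_id": sid,
                    "population": pop,
                    "taxon": "synthetic",
                    "clade": clade,
                    "latitude": lats[k],
                    "longitude": lons[k],
                    "introduced_candidate": False,
                }
            )

    introduced: list[str] = []
    if config.introduction is not None:
        intro = config.introduction
        k = labels.index(source_pop)
        if intro.destination_lat is not None:
            dlat, dlon = float(intro.destination_lat), float(intro.destination_lon)
        else:
            # place the introduction beyond the far end of the transect
            dlat = float(np.max(lats) + intro.offset_km / KM_PER_DEGREE_LAT)
            dlon = float(lons[k])
        ids.append(intro.sample_id)
        seqs.append(hap[source_pop])
        clades[intro.sample_id] = clades[labels[k] if config.samples_per_population == 1 else f"{labels[k]}a"]
        introduced.append(intro.sample_id)
        rows.append(
            {
                "sample_id": intro.sample_id,
                "population": intro.sample_id,
                "taxon": "synthetic",
                "clade": clades[intro.sample_id],
                "latitude": dlat,
                "longitude": dlon,
                "introduced_candidate": True,
            }
        )

    alignment = Alignment.from_sequences(ids, seqs)
    table = SampleTable(pd.DataFrame(rows))
    truth = SimTruth(
        slope=config.slope,
        intercept=config.intercept,
        kappa=config.kappa,
        noise=config.noise,
        seed=config.seed,
        clades=clades,
        introduced_ids=introduced,
        introduction_source=source_pop,
        branch_lengths=[float(x) for x in tree.branch_lengths()],
        tree_newick=tree.to_newick(),
        haplotype_shared_with=shared_with,
    )
    return alignment, table, truth


def write_dataset(
    out_dir: str | Path,
    alignment: Alignment,
    table: SampleTable,
    truth: SimTruth,
) -> dict[str, Path]:
    """Write FASTA alignment, TSV metadata, and JSON truth into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "alignment.fasta",
        "metadata": out / "samples.tsv",
        "truth": out / "truth.json",
    }
    write_alignment(alignment, paths["alignment"], format="fasta")
    write_sample_table(table, paths["metadata"])
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths
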