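"""Isolation-by-distance analysis over population distance matrices.

The workflow mirrors the comparative design used in mitochondrial
phylogeography: build population-level genetic (K80) and geographic
(great-circle km) distance matrices, test their association with a
one-tailed Mantel permutation test, fit an ordinary-least-squares line
of genetic on geographic distance over the matrix upper triangles, and
attach 95% confidence intervals from an independent-population-pair
bootstrap.  Each bootstrap replicate shuffles the populations, forms
floor(n/2) disjoint pairs, and refits the line on those independent
points, sidestepping the non-independence of full distance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignio import Alignment, SampleTable
from .distances import (
    DistanceMatrix,
    geographic_distance_matrix,
    pairwise_distance_matrix,
)

__all__ = [
    "IBDFit",
    "TaxonComparison",
    "BootstrapResult",
    "population_distance_matrices",
    "mantel_test",
    "ols_ibd_fit",
    "independent_pair_bootstrap",
    "fit_ibd",
    "compare_taxa",
]

DEFAULT_PERMUTATIONS = 9_999
DEFAULT_BOOTSTRAP = 1_000


def population_distance_matrices(
    alignment: Alignment,
    table: SampleTable,
    subset=None,
    *,
    model: str = "k80",
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Population-level genetic and geographic distance matrices.

    The genetic entry for two populations is the mean of the defined
    inter-individual distances between them; the geographic entry is the
    great-circle distance between the population coordinates (mean of
    the member samples' coordinates).  Populations with no defined
    genetic distance to any other population are dropped with a warning.
    """
    table.require_alignment(alignment)
    sub = table.subset(alignment.sample_ids)
    if subset is not None:
        keep = {str(p) for p in subset}
        sub = SampleTable(sub.df[sub.df.population.isin(keep)])
    pops = list(dict.fromkeys(sub.df.population))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    members = {p: sub.df[sub.df.population == p].sample_id.tolist() for p in pops}
    indiv = pairwise_distance_matrix(alignment.subset(sub.sample_ids), model=model)
    idx = {s: i for i, s in enumerate(indiv.labels)}

    n = len(pops)
    gvals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ia = [idx[s] for s in members[pops[i]]]
            ib = [idx[s] for s in members[pops[j]]]
            cells = indiv.values[np.ix_(ia, ib)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                gvals[i, j] = gvals[j, i] = np.nanmean(cells)

    # drop populations whose genetic distances are all undefined
    defined_any = [
        any(np.isfinite(gvals[i, j]) for j in range(n) if j != i) for i in range(n)
    ]
    if not all(defined_any):
        dropped = [p for p, ok in zip(pops, defined_any) if not ok]
        warnings.warn(f"dropping populations with no defined distances: {dropped}")
        keep_idx = [i for i, ok in enumerate(defined_any) if ok]
        pops = [pops[i] for i in keep_idx]
        gvals = gvals[np.ix_(keep_idx, keep_idx)]

    coords = sub.population_coordinates().set_index("population").loc[pops]
    genetic = DistanceMatrix(pops, gvals, units="substitutions/site")
    geographic = geographic_distance_matrix(
        pops, coords.latitude.to_numpy(), coords.longitude.to_numpy()
    )
    return genetic, geographic


def _aligned_triangles(d1: DistanceMatrix, d2: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    if set(d1.labels) != set(d2.labels):
        raise ValueError("distance matrices have different labels")
    d2 = d2.submatrix(d1.labels)
    return d1.condensed(), d2.condensed()


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """One-tailed (upper) Mantel permutation test.

    r is the Pearson correlation of the upper-triangle entries; each
    permutation jointly relabels the rows and columns of the second
    matrix; p = (1 + #{r_perm >= r_obs}) / (n_permutations + 1).
    """
    if d1.n < 3:
        raise ValueError("Mantel test needs at least 3 labels")
    x, _ = _aligned_triangles(d1, d2)
    d2o = d2.submatrix(d1.labels)
    if np.isnan(x).any() or np.isnan(d2o.values).any():
        raise ValueError("Mantel test requires fully defined matrices")
    y = d2o.condensed()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a distance matrix; Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    xc = x - x.mean()
    xden = np.sqrt((xc**2).sum())
    Y = d2o.values
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = Y[np.ix_(perm, perm)][iu]
        yc = yp - yp.mean()
        r = float((xc * yc).sum() / (xden * np.sqrt((yc**2).sum())))
        if r >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return r_obs, p


def ols_ibd_fit(
    genetic: DistanceMatrix, geographic: DistanceMatrix
) -> tuple[float, float]:
    """OLS slope and intercept of genetic on geographic upper-triangle points."""
    y, x = _aligned_triangles(genetic, geographic)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.unique(x).size < 2:
        raise ValueError("constant geographic distances; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


@dataclass
class BootstrapResult:
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    slopes: np.ndarray = field(repr=False)
    intercepts: np.ndarray = field(repr=False)


def independent_pair_bootstrap(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    n_replicates: int = DEFAULT_BOOTSTRAP,
    seed: int | np.random.Generator | None = None,
    *,
    max_redraw_rounds: int = 100,
) -> BootstrapResult:
    """Percentile CIs for the IBD line from independent population pairs.

    Each replicate shuffles the population order, forms floor(n/2)
    disjoint consecutive pairs, takes each pair's (geographic, genetic)
    distances as one point, and fits an OLS line.  CIs are the
    2.5th/97.5th percentiles over replicates.  Replicates with constant
    geographic values (or fewer than two usable points) are redrawn, up
    to a capped number of rounds.
    """
    n = genetic.n
    if n < 4:
        raise ValueError("independent-pair bootstrap needs at least 4 populations")
    if n_replicates < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    geo = geographic.submatrix(genetic.labels).values
    gen = genetic.values
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    k = n // 2
    slopes = np.full(n_replicates, np.nan)
    intercepts = np.full(n_replicates, np.nan)
    todo = np.arange(n_replicates)
    rounds = 0
    while todo.size and rounds < max_redraw_rounds:
        m = todo.size
        perm = np.argsort(rng.random((m, n)), axis=1)
        i0, i1 = perm[:, 0 : 2 * k : 2], perm[:, 1 : 2 * k : 2]
        x = geo[i0, i1]
        y = gen[i0, i1]
        ok = np.isfinite(x) & np.isfinite(y)
        cnt = ok.sum(axis=1)
        xm = np.where(ok, x, 0.0)
        ym = np.where(ok, y, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            xbar = xm.sum(axis=1) / cnt
            ybar = ym.sum(axis=1) / cnt
            sxx = (np.where(ok, (x - xbar[:, None]) ** 2, 0.0)).sum(axis=1)
            sxy = (
                np.where(ok, (x - xbar[:, None]) * (y - ybar[:, None]), 0.0)
            ).sum(axis=1)
            b = sxy / sxx
            a = ybar - b * xbar
        good = (cnt >= 2) & (sxx > 0)
        slopes[todo[good]] = b[good]
        intercepts[todo[good]] = a[good]
        todo = todo[~good]
        rounds += 1
    if todo.size:
        warnings.warn(
            f"{todo.size} bootstrap replicates remained degenerate after "
            f"{max_redraw_rounds} redraw rounds; excluded from percentiles"
        )
    ok = np.isfinite(slopes)
    slope_ci = tuple(np.percentile(slopes[ok], [2.5, 97.5]))
    intercept_ci = tuple(np.percentile(intercepts[ok], [2.5, 97.5]))
    return BootstrapResult(slope_ci, intercept_ci, slopes[ok], intercepts[ok])


@dataclass
class IBDFit:
    """Mantel statistic, OLS line, and bootstrap CIs for one taxon."""

    label: str
    n_populations: int
    mantel_r: float
    mantel_p: float
    n_permutations: int
    slope: float  # substitutions/site per km
    intercept: float  # substitutions/site
    bootstrap_replicates: int
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    seed: int | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.mantel_r <= 1.0 + 1e-9:
            raise ValueError("Mantel r outside [-1, 1]")
        if not 0.0 < self.mantel_p <= 1.0:
            raise ValueError("Mantel p outside (0, 1]")
        for lo, hi in (self.slope_ci, self.intercept_ci):
            if lo > hi:
                raise ValueError("confidence interval bounds reversed")


def fit_ibd(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    *,
    label: str = "",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    n_replicates: int = DEFAULT_BOOTSTRAP,
    seed: int | None = None,
) -> IBDFit:
    """Run the full IBD analysis for one taxon's population matrices."""
    ss = np.random.SeedSequence(seed)
    rng_mantel, rng_boot = (np.random.default_rng(s) for s in ss.spawn(2))
    r, p = mantel_test(geographic, genetic, n_permutations, rng_mantel)
    slope, intercept = ols_ibd_fit(genetic, geographic)
    boot = independent_pair_bootstrap(genetic, geographic, n_replicates, rng_boot)
    return IBDFit(
        label=label,
        n_populations=genetic.n,
        mantel_r=r,
        mantel_p=p,
        n_permutations=n_permutations,
        slope=slope,
        intercept=intercept,
        bootstrap_replicates=n_replicates,
        slope_ci=boot.slope_ci,
        intercept_ci=boot.intercept_ci,
        seed=seed,
    )


@dataclass
class TaxonComparison:
    """Closed-interval overlap of two taxa's slope and intercept CIs."""

    labels: tuple[str, str]
    slope_cis_overlap: bool
    intercept_cis_overlap: bool


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def compare_taxa(fit_a: IBDFit, fit_b: IBDFit) -> TaxonComparison:
    return TaxonComparison(
        labels=(fit_a.label, fit_b.label),
        slope_cis_overlap=_intervals_overlap(fit_a.slope_ci, fit_b.slope_ci),
        intercept_cis_overlap=_intervals_overlap(fit_a.intercept_ci, fit_b.intercept_ci),
    )
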