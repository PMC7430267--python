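"""Screen for candidate introduced samples.

An introduced population betrays itself by carrying a haplotype that is
(nearly) identical to haplotypes from localities far outside normal
dispersal range: mitochondrial haplotypes in low-vagility terrestrial
salamanders occupy ranges of at most a few tens of kilometres, so a
(near-)exact match hundreds of kilometres away is evidence of
human-mediated transport rather than natural range.  The screen
operationalizes this as a two-threshold rule: a sample is flagged when
its minimum genetic distance to any non-focal sample is at most
``genetic_threshold`` (default 0.01 substitutions/site, uncorrected
p-distance) *and* the geographically nearest of those minimum-distance
matches lies at least ``geographic_threshold`` km away (default 100 km,
far beyond observed haplotype spans).

Samples from the focal sample's own population are excluded from its
reference set: population-mates share provenance, so an introduced
population cannot vouch for itself through its own co-sampled
individuals.  Genetic evidence alone is symmetric — when a haplotype
occurs at exactly two mutually distant localities, both ends satisfy
the rule and both are reported; field knowledge of the native range (or
local haplotype sharing around the true source) breaks the tie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignio import Alignment, SampleTable
from .distances import great_circle_km, pairwise_distance_matrix

__all__ = [
    "IntroductionReport",
    "nearest_genetic_neighbors",
    "screen_introductions",
    "DEFAULT_GENETIC_THRESHOLD",
    "DEFAULT_GEOGRAPHIC_THRESHOLD",
]

DEFAULT_GENETIC_THRESHOLD = 0.01  # substitutions/site
DEFAULT_GEOGRAPHIC_THRESHOLD = 100.0  # km


def nearest_genetic_neighbors(
    alignment: Alignment,
    table: SampleTable,
    focal_id: str,
    *,
    model: str = "p",
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Non-focal samples ranked by genetic distance to the focal sample.

    Ties are broken by sample id; all tied samples are reported.  The
    result columns are ``sample_id, population, distance, km`` where
    ``km`` is the great-circle distance from the focal locality.
    """
    table.require_alignment(alignment)
    if focal_id not in alignment.sample_ids:
        raise KeyError(f"focal id not in alignment: {focal_id!r}")
    others = [
        s for s in alignment.sample_ids if s != focal_id and s not in set(exclude)
    ]
    if not others:
        raise ValueError("no non-focal samples to compare against")
    dm = pairwise_distance_matrix(alignment.subset([focal_id] + others), model=model)
    dists = dm.values[0, 1:]
    if np.all(np.isnan(dists)):
        raise ValueError(f"all distances from {focal_id!r} are undefined")
    flat, flon = table.coordinates(focal_id)
    rows = []
    for sid, d in zip(others, dists):
        if np.isnan(d):
            continue
        lat, lon = table.coordinates(sid)
        rows.append(
            {
                "sample_id": sid,
                "population": table.row(sid).population,
                "distance": float(d),
                "km": great_circle_km(flat, flon, lat, lon),
            }
        )
    df = pd.DataFrame(rows).sort_values(["distance", "sample_id"]).reset_index(drop=True)
    return df


@dataclass
class IntroductionReport:
    """Per-focal-sample nearest-haplotype evidence and the screen's verdict."""

    table: pd.DataFrame = field(repr=False)
    genetic_threshold: float = DEFAULT_GENETIC_THRESHOLD
    geographic_threshold: float = DEFAULT_GEOGRAPHIC_THRESHOLD
    model: str = "p"

    @property
    def flagged_ids(self) -> list[str]:
        return self.table[self.table.flagged].sample_id.tolist()

    def row(self, sample_id: str) -> pd.Series:
        hit = self.table[self.table.sample_id == sample_id]
        if hit.empty:
            raise KeyError(f"sample not screened: {sample_id!r}")
        return hit.iloc[0]


def _haplotype_span_km(
    alignment: Alignment, table: SampleTable, member_ids: list[str]
) -> float:
    """Maximum great-circle km between localities sharing one haplotype."""
    coords = np.array([table.coordinates(s) for s in member_ids])
    if len(coords) < 2:
        return 0.0
    lat, lon = coords[:, 0], coords[:, 1]
    km = great_circle_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    return float(np.max(km))


def screen_introductions(
    alignment: Alignment,
    table: SampleTable,
    genetic_threshold: float = DEFAULT_GENETIC_THRESHOLD,
    geographic_threshold: float = DEFAULT_GEOGRAPHIC_THRESHOLD,
    *,
    model: str = "p",
    focal_ids=None,
    exclude_reference: tuple[str, ...] = (),
) -> IntroductionReport:
    """Apply the two-threshold introduction screen to each focal sample.

    By default every sample is screened against all others;
    ``focal_ids`` restricts the screened set and ``exclude_reference``
    removes samples (e.g. island populations of debated status) from
    the reference set without screening them.
    """
    if not genetic_threshold > 0 or not geographic_threshold > 0:
        raise ValueError("thresholds must be positive")
    table.require_alignment(alignment)
    focal = list(focal_ids) if focal_ids is not None else list(alignment.sample_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dm = pairwise_distance_matrix(alignment, model=model)
    idx = {s: i for i, s in enumerate(dm.labels)}
    excluded = set(exclude_reference)
    pop_of = {s: table.row(s).population for s in dm.labels}
    rows = []
    for sid in focal:
        others = [
            s
            for s in dm.labels
            if s != sid and s not in excluded and pop_of[s] != pop_of[sid]
        ]
        dists = np.array([dm.values[idx[sid], idx[s]] for s in others])
        defined = np.isfinite(dists)
        if not defined.any():
            raise ValueError(f"all distances from {sid!r} are undefined")
        dmin = float(np.nanmin(dists))
        at_min = [s for s, d in zip(others, dists) if np.isfinite(d) and d <= dmin + 1e-12]
        flat, flon = table.coordinates(sid)
        match_km = {
            s: great_circle_km(flat, flon, *table.coordinates(s)) for s in at_min
        }
        nearest_km = min(match_km.values())
        # localities sharing the focal haplotype exactly (distance 0), focal included
        sharing = [sid] + [s for s, d in zip(others, dists) if d == 0.0]
        span = _haplotype_span_km(alignment, table, sharing)
        flagged = dmin <= genetic_threshold and nearest_km >= geographic_threshold
        reason = (
            f"min {model}-distance {dmin:.4f} <= {genetic_threshold} and nearest "
            f"match {nearest_km:.0f} km >= {geographic_threshold} km"
            if flagged
            else "no anomalous haplotype match"
        )
        rows.append(
            {
                "sample_id": sid,
                "population": table.row(sid).population,
                "min_distance": dmin,
                "match_ids": at_min,
                "match_populations": sorted(
                    {table.row(s).population for s in at_min}
                ),
                "match_km": [match_km[s] for s in at_min],
                "nearest_match_km": nearest_km,
                "haplotype_span_km": span,
                "flagged": flagged,
                "reason": reason,
            }
        )
    return IntroductionReport(
        pd.DataFrame(rows),
        genetic_threshold=genetic_threshold,
        geographic_threshold=geographic_threshold,
        model=model,
    )
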