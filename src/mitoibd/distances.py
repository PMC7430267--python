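"""Pairwise genetic and geographic distances.

Genetic distances are computed per sequence pair from transition and
transversion proportions under the Kimura two-parameter (K80) model,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the proportions of transition (A<->G, C<->T) and
transversion differences among sites that are unambiguous A/C/G/T in
both sequences (pairwise deletion).  The uncorrected p-distance
(P + Q) is available as an alternative model.  Geographic distances are
great-circle (haversine) kilometres on a sphere of mean Earth radius.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .alignio import Alignment

__all__ = [
    "SitePairCounts",
    "DistanceMatrix",
    "count_site_pairs",
    "k80_distance",
    "p_distance",
    "pairwise_distance_matrix",
    "great_circle_km",
    "geographic_distance_matrix",
    "standardize_rate",
    "EARTH_RADIUS_KM",
    "DEFAULT_ND4_TO_CYTB",
]

logger = logging.getLogger(__name__)

#: Mean Earth radius (IUGG) used for great-circle distances.
EARTH_RADIUS_KM = 6371.0088

#: Relative-rate factor converting nd4 distances onto the cytb scale.
DEFAULT_ND4_TO_CYTB = 1.41

# Base encoding: A=0, C=1, G=2, T=3; transitions pair codes of equal parity.
_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


@dataclass(frozen=True)
class SitePairCounts:
    """Transition/transversion counts for one sequence pair (pairwise deletion)."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if min(self.n_compared, self.n_transitions, self.n_transversions) < 0:
            raise ValueError("negative site-pair counts")
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise ValueError("more differences than compared sites")

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_compared

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_compared


def encode_alignment(alignment: Alignment) -> np.ndarray:
    """Encode characters as uint8 codes (A,C,G,T -> 0..3; everything else 255)."""
    # '<U1' view -> uint32 code points; clip to ASCII for table lookup
    chars = np.ascontiguousarray(alignment.characters)
    codepoints = chars.view(np.uint32).reshape(chars.shape)
    return _CODE[np.minimum(codepoints, 127)]


def _pair_counts(row_a: np.ndarray, row_b: np.ndarray) -> SitePairCounts:
    ok = (row_a < 4) & (row_b < 4)
    a, b = row_a[ok], row_b[ok]
    diff = a != b
    ts = diff & ((a & 1) == (b & 1))
    return SitePairCounts(int(ok.sum()), int(ts.sum()), int((diff & ~ts).sum()))


def count_site_pairs(seq_a: str, seq_b: str) -> SitePairCounts:
    """Count compared sites, transitions and transversions for two sequences.

    Sites with a gap or ambiguity code in either sequence are excluded
    from all counts.
    """
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    if a.size != b.size:
        raise ValueError(f"sequence lengths differ: {a.size} vs {b.size}")
    return _pair_counts(_CODE[np.minimum(a, 127)], _CODE[np.minimum(b, 127)])


def k80_distance(counts: SitePairCounts) -> float:
    """Kimura two-parameter distance; NaN when outside the model's domain."""
    if counts.n_compared == 0:
        warnings.warn("no comparable sites; K80 distance undefined", stacklevel=2)
        return float("nan")
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def p_distance(counts: SitePairCounts) -> float:
    """Uncorrected proportion of differing sites among compared sites."""
    if counts.n_compared == 0:
        warnings.warn("no comparable sites; p-distance undefined", stacklevel=2)
        return float("nan")
    return (counts.n_transitions + counts.n_transversions) / counts.n_compared


_MODEL_FUNCS = {"k80": k80_distance, "p": p_distance}


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with NaN marking undefined cells."""

    labels: list[str]
    values: np.ndarray
    units: str = "substitutions/site"

    def __post_init__(self) -> None:
        self.labels = [str(s) for s in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix, True where the distance is undefined."""
        return np.isnan(self.values)

    @property
    def n_undefined(self) -> int:
        """Number of undefined unordered pairs."""
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.values[iu]).sum())

    def get(self, label_a: str, label_b: str) -> float:
        i, j = self.labels.index(label_a), self.labels.index(label_b)
        return float(self.values[i, j])

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(str(l)) for l in labels]
        return DistanceMatrix(
            [str(l) for l in labels], self.values[np.ix_(idx, idx)], units=self.units
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries (row-major), NaN included."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.units == other.units
            and bool(np.allclose(self.values, other.values, equal_nan=True))
        )

    def allclose(self, other: "DistanceMatrix", atol: float = 1e-9) -> bool:
        return self.labels == other.labels and bool(
            np.allclose(self.values, other.values, atol=atol, equal_nan=True)
        )


def pairwise_distance_matrix(alignment: Alignment, model: str = "k80") -> DistanceMatrix:
    """All-pairs genetic distance matrix under ``k80`` or ``p``.

    Cells outside the K80 domain (or with zero comparable sites) are
    undefined (NaN); their count is reported in the module log.
    """
    if model not in _MODEL_FUNCS:
        raise ValueError(f"unknown model: {model!r}")
    if alignment.n_samples < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    func = _MODEL_FUNCS[model]
    codes = encode_alignment(alignment)
    n = alignment.n_samples
    values = np.zeros((n, n), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                d = func(_pair_counts(codes[i], codes[j]))
                values[i, j] = values[j, i] = d
    matrix = DistanceMatrix(alignment.sample_ids, values)
    if matrix.n_undefined:
        logger.warning(
            "%d of %d pairwise %s distances undefined (masked)",
            matrix.n_undefined, n * (n - 1) // 2, model,
        )
    return matrix


def _check_coords(lat: np.ndarray, lon: np.ndarray) -> None:
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude out of [-90, 90]")
    if np.any((lon < -180) | (lon > 180)):
        raise ValueError("longitude out of [-180, 180]")


def great_circle_km(lat1, lon1, lat2, lon2) -> float | np.ndarray:
    """Haversine great-circle distance in km (sphere radius 6371.0088 km)."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def geographic_distance_matrix(labels, latitudes, longitudes) -> DistanceMatrix:
    """Great-circle distance matrix over labeled coordinates."""
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    values = great_circle_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    values = np.asarray(values)
    np.fill_diagonal(values, 0.0)
    # enforce exact symmetry against floating-point asymmetry
    values = (values + values.T) / 2.0
    return DistanceMatrix(list(labels), values, units="km")


def standardize_rate(matrix: DistanceMatrix, factor: float = DEFAULT_ND4_TO_CYTB) -> DistanceMatrix:
    """Divide all defined distances by a relative-rate factor.

    Converts distances measured at a faster-evolving locus (e.g. nd4)
    onto the reference (cytb) scale; the bundled default factor is 1.41.
    """
    if not factor > 0:
        raise ValueError(f"rate factor must be positive, got {factor}")
    if matrix.units != "substitutions/site":
        raise ValueError("rate standardization applies to substitutions/site matrices")
    return DistanceMatrix(matrix.labels, matrix.values / factor, units=matrix.units)
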