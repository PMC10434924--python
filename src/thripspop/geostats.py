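"""Geographic distances, Mantel test, mode homogeneity, and sampling design.

Great-circle distances between sampling sites use the haversine formula with
the mean Earth radius (6371.0088 km).  The Mantel test correlates the
off-diagonal entries of two labeled distance matrices and builds its null by
jointly permuting the rows and columns of the second matrix; the p-value
uses the add-one rule (the observed statistic counts as one of its own
permutations), so p is never zero.  Reproductive-mode homogeneity across
locations is a Pearson chi-square on a 2 x L count table without continuity
correction.  The sampling-design helpers answer "how likely is a haplotype
of frequency f to appear in a sample of n" (1 - (1-f)^n) and its inverse.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics.pairwise import haversine_distances

from .distances import DistanceMatrix

EARTH_RADIUS_KM = 6371.0088


def geo_distance_matrix(locations) -> DistanceMatrix:
    """Haversine distance matrix in km from decimal-degree coordinates.

    ``locations`` is a DataFrame with columns location/latitude/longitude or
    a sequence of (label, latitude, longitude) triples.  Repeated samples of
    the same site (identical coordinates) get distance zero.
    """
    if isinstance(locations, pd.DataFrame):
        triples = list(zip(locations["location"], locations["latitude"],
                           locations["longitude"]))
    else:
        triples = [tuple(t) for t in locations]
    labels = [t[0] for t in triples]
    lat = np.array([t[1] for t in triples], dtype=float)
    lon = np.array([t[2] for t in triples], dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude out of [-90, 90]")
    if np.any((lon < -180) | (lon > 180)):
        raise ValueError("longitude out of [-180, 180]")
    coords = np.radians(np.column_stack([lat, lon]))
    km = haversine_distances(coords) * EARTH_RADIUS_KM
    km = (km + km.T) / 2.0  # exact symmetry
    np.fill_diagonal(km, 0.0)
    return DistanceMatrix(labels, km, model="geo_km", deletion="pairwise")


@dataclasses.dataclass
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int
    alternative: str


def _offdiag(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel_test(
    X: DistanceMatrix | np.ndarray,
    Y: DistanceMatrix | np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
) -> MantelResult:
    """Permutation test of the correlation between two distance matrices.

    r is the Pearson correlation over upper-triangle off-diagonal entries;
    the null permutes the labels (rows and columns jointly) of Y.  The
    default is two-sided on |r|; ``alternative='greater'`` gives the
    one-sided test some population-genetics packages report.
    """
    xv = X.values if isinstance(X, DistanceMatrix) else np.asarray(X, float)
    yv = Y.values if isinstance(Y, DistanceMatrix) else np.asarray(Y, float)
    if isinstance(X, DistanceMatrix) and isinstance(Y, DistanceMatrix):
        if X.labels != Y.labels:
            raise ValueError("matrix labels differ")
    if xv.shape != yv.shape or xv.shape[0] != xv.shape[1]:
        raise ValueError("dimension mismatch between matrices")
    if alternative not in ("two-sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = xv.shape[0]
    x = _offdiag(xv)
    if x.std() == 0 or _offdiag(yv).std() == 0:
        raise ValueError("constant distance matrix: correlation undefined")

    def corr(perm: np.ndarray) -> float:
        y = _offdiag(yv[np.ix_(perm, perm)])
        return float(np.corrcoef(x, y)[0, 1])

    identity = np.arange(n)
    r_obs = corr(identity)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        r_perm = corr(rng.permutation(n))
        if alternative == "two-sided":
            if abs(r_perm) >= abs(r_obs):
                exceed += 1
        else:
            if r_perm >= r_obs:
                exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return MantelResult(r_obs, r_obs**2, p, n_permutations, seed, alternative)


@dataclasses.dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame
    n: int


def mode_homogeneity_chisq(mode_counts_by_location) -> ChiSquareResult:
    """Pearson chi-square for homogeneity of the two reproductive modes
    across locations (2 x L table, expected counts from the margins, no
    continuity correction; df = L - 1).

    ``mode_counts_by_location`` is a DataFrame (rows = 2 modes, columns =
    locations) or a 2 x L array.  Locations with zero total are dropped with
    a warning; individuals with undetermined mode must be excluded upstream.
    """
    table = (
        mode_counts_by_location.copy()
        if isinstance(mode_counts_by_location, pd.DataFrame)
        else pd.DataFrame(np.asarray(mode_counts_by_location))
    )
    if table.shape[0] != 2:
        raise ValueError(f"expected a 2 x L table, got {table.shape}")
    if (table.values < 0).any():
        raise ValueError("negative counts")
    empty = table.columns[table.sum(axis=0) == 0]
    if len(empty):
        warnings.warn(f"dropping zero-total locations: {list(empty)}")
        table = table.drop(columns=empty)
    if table.shape[1] < 2:
        raise ValueError("need at least two non-empty locations")
    chi2, p, df, _ = stats.chi2_contingency(table.values, correction=False)
    return ChiSquareResult(float(chi2), int(df), float(p), table,
                           int(table.values.sum()))


def detection_probability(freq: float, n: int) -> float:
    """Probability that a haplotype at population frequency ``freq`` shows up
    at least once in a random sample of ``n`` individuals: 1 - (1-f)^n."""
    if not 0 < freq <= 1:
        raise ValueError(f"frequency must be in (0, 1], got {freq}")
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    return 1.0 - (1.0 - freq) ** n


def min_sample_size(freq: float, confidence: float = 0.95) -> int:
    """Smallest n with detection probability >= confidence."""
    if not 0 < freq <= 1:
        raise ValueError(f"frequency must be in (0, 1], got {freq}")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if freq == 1.0:
        return 1
    n = math.ceil(math.log(1.0 - confidence) / math.log(1.0 - freq))
    while detection_probability(freq, n) < confidence:  # guard rounding
        n += 1
    while n > 1 and detection_probability(freq, n - 1) >= confidence:
        n -= 1
    return n
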