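"""Angle histograms, torsional-state peak counting, and distribution
differences for backbone torsional pairs.

Angles live on the circle, discretized into 60 equal 6-degree bins on
(-180, 180] (bin k covers [-180+6k, -180+6(k+1)), the last bin closed at
180). Peaks of a 1D distribution are "collective bins": runs of bins
between boundary bins found from the cyclic neighbor differences
delta_n = p(n) - p(n-1); a collective bin whose total probability
exceeds 0.1 counts as a distribution peak, so the number of peaks
proxies the number of occupied torsional states. Joint (2D)
distributions are scanned for strict 8-neighbor local maxima on the
torus; tentative maxima closer than 3 bins on both axes merge into one
peak. The distribution difference Delta p(m,n) = p(m,n) - p_x(m) p_y(n)
vanishes identically for independent torsions; the geometry of its
positive peaks diagnoses whether the pair's linear coupling is
homogeneous (peaks collinear) or heterogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TorsionSeries

__all__ = [
    "Distribution1D",
    "Distribution2D",
    "PeakSet",
    "histogram_1d",
    "count_peaks_1d",
    "joint_histogram",
    "count_joint_peaks",
    "distribution_difference",
    "heterogeneity_score",
    "bin_angles",
]

DEFAULT_BINS = 60


def bin_angles(angles: np.ndarray, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Map angles in (-180, 180] to bin indices 0..n_bins-1.

    An angle of exactly 180 falls in the last bin.
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle series")
    if np.any(a <= -180.0) or np.any(a > 180.0):
        raise ValueError("angles must lie in (-180, 180] degrees")
    width = 360.0 / n_bins
    idx = np.floor((a + 180.0) / width).astype(int)
    idx[idx == n_bins] = n_bins - 1
    return idx


@dataclass
class Distribution1D:
    """Normalized histogram of one torsion over n_bins cyclic bins."""

    p: np.ndarray
    M: int

    @property
    def n_bins(self) -> int:
        return self.p.size

    def validate(self) -> None:
        if abs(self.p.sum() - 1.0) > 1e-9 or np.any(self.p < 0):
            raise ValueError("distribution not normalized")


@dataclass
class Distribution2D:
    """Normalized joint histogram of a torsion pair on a toroidal grid."""

    p: np.ndarray  # shape (n_bins, n_bins); axis 0 = x bin, axis 1 = y bin
    M: int

    @property
    def n_bins(self) -> int:
        return self.p.shape[0]

    @property
    def marginal_x(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def marginal_y(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @property
    def delta_p(self) -> np.ndarray:
        return distribution_difference(self)


@dataclass
class PeakSet:
    """Detected peaks of a 1D or joint 2D distribution.

    For 1D: ``boundaries`` are boundary bin indices, ``collective_bins``
    the (member bins, mass) of each collective bin, and peaks the
    collective bins with mass > threshold. For 2D: ``tentative`` the
    strict local maxima, ``groups`` the transitively merged groups.
    """

    ndim: int
    n_peaks: int
    boundaries: list[int] = field(default_factory=list)
    collective_bins: list[tuple[list[int], float]] = field(default_factory=list)
    tentative: list[tuple[int, int]] = field(default_factory=list)
    groups: list[list[tuple[int, int]]] = field(default_factory=list)
    degenerate_plateau: bool = False


def histogram_1d(series: TorsionSeries | np.ndarray, n_bins: int = DEFAULT_BINS) -> Distribution1D:
    """60-bin (by default) normalized histogram of one torsion series."""
    angles = series.angles if isinstance(series, TorsionSeries) else np.asarray(series)
    idx = bin_angles(angles, n_bins)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return Distribution1D(p=counts / idx.size, M=idx.size)


def count_peaks_1d(dist: Distribution1D, peak_threshold: float = 0.1) -> PeakSet:
    """Count torsional states of a 1D distribution by the collective-bin rule.

    Cyclic differences delta_n = p(n) - p(n-1) (delta_0 wraps to the
    last bin). Ignoring zero differences, bin i is a boundary when
    delta_i < 0 and the next nonzero delta (cyclically) is positive.
    Bins between consecutive boundaries merge into collective bins; a
    collective bin with probability strictly greater than
    ``peak_threshold`` is a peak. A distribution with no boundaries
    (e.g. uniform) is one collective bin of mass 1, hence one peak.
    """
    p = dist.p
    n = p.size
    delta = p - np.roll(p, 1)
    nz = np.nonzero(delta)[0]
    boundaries: list[int] = []
    if nz.size:
        for k, i in enumerate(nz):
            if delta[i] < 0:
                j = nz[(k + 1) % nz.size]
                if delta[j] > 0:
                    boundaries.append(int(i))
    if not boundaries:
        collective = [(list(range(n)), float(p.sum()))]
    else:
        # bins from one boundary up to (excluding) the next form a collective bin
        bs = sorted(boundaries)
        collective = []
        for k, b in enumerate(bs):
            nxt = bs[(k + 1) % len(bs)]
            if nxt > b:
                members = list(range(b, nxt))
            else:  # wrap
                members = list(range(b, n)) + list(range(0, nxt))
            collective.append((members, float(p[members].sum())))
    n_peaks = sum(1 for _, mass in collective if mass > peak_threshold)
    return PeakSet(
        ndim=1,
        n_peaks=n_peaks,
        boundaries=sorted(boundaries),
        collective_bins=collective,
    )


def joint_histogram(
    x: TorsionSeries | np.ndarray,
    y: TorsionSeries | np.ndarray,
    n_bins: int = DEFAULT_BINS,
) -> Distribution2D:
    """Joint normalized histogram of two torsion series on the n_bins^2 torus."""
    ax = x.angles if isinstance(x, TorsionSeries) else np.asarray(x)
    ay = y.angles if isinstance(y, TorsionSeries) else np.asarray(y)
    if ax.size != ay.size:
        raise ValueError(f"series length mismatch: {ax.size} vs {ay.size}")
    ix = bin_angles(ax, n_bins)
    iy = bin_angles(ay, n_bins)
    counts = np.zeros((n_bins, n_bins))
    np.add.at(counts, (ix, iy), 1.0)
    return Distribution2D(p=counts / ax.size, M=ax.size)


def _strict_local_maxima(grid: np.ndarray) -> list[tuple[int, int]]:
    """Bins strictly greater than all 8 toroidal neighbors."""
    mask = np.ones_like(grid, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            mask &= grid > np.roll(np.roll(grid, di, axis=0), dj, axis=1)
    return [tuple(map(int, ij)) for ij in np.argwhere(mask)]


def _merge_peaks(
    maxima: list[tuple[int, int]], n_bins: int, merge_radius: int
) -> list[list[tuple[int, int]]]:
    """Transitive closure of pairwise merges by cyclic index distance."""

    def cyc(a: int, b: int) -> int:
        d = abs(a - b) % n_bins
        return min(d, n_bins - d)

    parent = list(range(len(maxima)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(maxima)):
        for j in range(i + 1, len(maxima)):
            (xi, yi), (xj, yj) = maxima[i], maxima[j]
            if cyc(xi, xj) <= merge_radius and cyc(yi, yj) <= merge_radius:
                parent[find(i)] = find(j)
    groups: dict[int, list[tuple[int, int]]] = {}
    for i, m in enumerate(maxima):
        groups.setdefault(find(i), []).append(m)
    return list(groups.values())


def count_joint_peaks(dist: Distribution2D, merge_radius: int = 3) -> PeakSet:
    """Count joint-distribution peaks of a pair.

    Tentative peaks are bins strictly greater than all 8 toroidal
    neighbors; two tentative peaks whose cyclic index differences on
    BOTH dimensions are <= merge_radius merge (closure taken over
    chains), because sub-24-degree splits within one basin are not
    torsional state transitions. An exact plateau (no strict maximum)
    is flagged degenerate.
    """
    maxima = _strict_local_maxima(dist.p)
    if not maxima:
        return PeakSet(ndim=2, n_peaks=0, degenerate_plateau=True)
    groups = _merge_peaks(maxima, dist.n_bins, merge_radius)
    return PeakSet(ndim=2, n_peaks=len(groups), tentative=maxima, groups=groups)


def distribution_difference(dist: Distribution2D) -> np.ndarray:
    """Delta p(m,n) = p(m,n) - p_x(m) p_y(n); sums to zero."""
    return dist.p - np.outer(dist.marginal_x, dist.marginal_y)


def heterogeneity_score(
    dist: Distribution2D,
    noise_floor: float | None = None,
    residual_tolerance: float = 1.5,
    merge_radius: int = 3,
) -> dict:
    """Score the homogeneity of a pair's linear coupling from Delta p peaks.

    Positive peaks of Delta p = p(x,y) - p(x)p(y) are found with the 2D
    peak rule applied to max(Delta p, 0). If the peak centers fall
    approximately on one straight line the observed linear correlation
    is homogeneous; if more than one line segment is needed the pair's
    linear correlations are heterogeneous — the mechanism behind
    nonlinear pair correlation. No positive peak above the noise floor
    means the torsions are effectively independent.

    Peak centers are unwrapped around their circular mean before a
    total-least-squares line fit; the verdict compares the RMS
    perpendicular residual (in bins) to ``residual_tolerance``.

    Returns a dict with keys: verdict ('independent' | 'homogeneous' |
    'heterogeneous'), peak_centers (bin coordinates), residual (bins),
    n_line_segments (1 if homogeneous else number of peaks - 1 as an
    upper bound on segments needed).
    """
    n_bins = dist.n_bins
    if noise_floor is None:
        # 5x the Poisson noise scale of a uniformly occupied cell,
        # sqrt(p/M) with p = 1/n_bins^2: above the expected maximum of
        # ~n_bins^2 independent noise cells (~4 sigma), below any real
        # state-occupancy excess.
        noise_floor = 5.0 * np.sqrt(1.0 / (n_bins**2 * dist.M))
    dpos = np.maximum(distribution_difference(dist), 0.0)
    maxima = [ij for ij in _strict_local_maxima(dpos) if dpos[ij] > noise_floor]
    if not maxima:
        return {
            "verdict": "independent",
            "peak_centers": [],
            "residual": 0.0,
            "n_line_segments": 0,
        }
    groups = _merge_peaks(maxima, n_bins, merge_radius)
    # mass-weighted center of each merged group, on the torus
    centers = []
    for g in groups:
        w = np.array([dpos[ij] for ij in g])
        ang = np.array(g, dtype=float) * (2 * np.pi / n_bins)
        z = (w[:, None] * np.exp(1j * ang)).sum(axis=0) / w.sum()
        centers.append(np.angle(z) * n_bins / (2 * np.pi) % n_bins)
    centers = np.array(centers)

    if len(centers) <= 2:
        return {
            "verdict": "homogeneous",
            "peak_centers": centers,
            "residual": 0.0,
            "n_line_segments": 1,
        }

    # unwrap each coordinate around the circular mean of the centers
    unwrapped = np.empty_like(centers)
    for d in range(2):
        ang = centers[:, d] * (2 * np.pi / n_bins)
        mean = np.angle(np.exp(1j * ang).mean())
        dev = np.angle(np.exp(1j * (ang - mean)))
        unwrapped[:, d] = dev * n_bins / (2 * np.pi)

    # total least squares: principal axis of the centered cloud
    c = unwrapped - unwrapped.mean(axis=0)
    _, s, _ = np.linalg.svd(c, full_matrices=False)
    residual = float(s[-1] / np.sqrt(len(centers)))  # RMS perpendicular distance
    homogeneous = residual <= residual_tolerance
    return {
        "verdict": "homogeneous" if homogeneous else "heterogeneous",
        "peak_centers": centers,
        "residual": residual,
        "n_line_segments": 1 if homogeneous else max(2, len(centers) - 1),
    }


def write_grid_tsv(path, grid: np.ndarray) -> None:
    """Export a distribution or Delta p grid as a TSV matrix (row = x bin)."""
    np.savetxt(path, grid, delimiter="\t", fmt="%.8g")
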