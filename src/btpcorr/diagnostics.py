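"""Convergence, permutation-null and trajectory-subset diagnostics.

Sampling checks for the correlation analysis: (1) a torsion's marginal
distribution is called converged when the K-L divergences between three
contiguous equal thirds of its trajectory all stay below 0.2 nats;
(2) a permutation null — recomputing r and MI after independently
resampling the two series' snapshot indices — bounds the spurious
correlation attributable purely to finite sample size; (3) splitting a
trajectory into equal subsets shows how much of a pair's correlation is
carried by state transitions occurring on time scales comparable to the
subset length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import circular_correlation, mutual_information
from .distributions import DEFAULT_BINS, Distribution1D, count_joint_peaks, histogram_1d, joint_histogram
from .geometry import TorsionSeries

__all__ = [
    "ConvergenceReport",
    "SubsetResult",
    "kl_divergence",
    "convergence_check",
    "permutation_null",
    "subset_analysis",
    "thin_snapshots",
]


@dataclass
class ConvergenceReport:
    """Per-torsion subset K-L divergences and converged verdicts."""

    kl_values: dict[int, tuple[float, float, float]]  # torsion index -> 3 pairwise K-L
    converged: dict[int, bool]
    threshold: float = 0.2

    @property
    def fraction_not_converged(self) -> float:
        if not self.converged:
            return 0.0
        return 1.0 - sum(self.converged.values()) / len(self.converged)


@dataclass
class SubsetResult:
    """Per-subset (MI, r, joint peak count) with the full-set reference."""

    subsets: list[dict] = field(default_factory=list)
    full_MI: float = 0.0
    full_r: float = 0.0


def kl_divergence(
    p: Distribution1D | np.ndarray,
    q: Distribution1D | np.ndarray,
    epsilon: float | None = None,
) -> float:
    """K-L divergence sum p ln(p/q) in nats, with epsilon-regularized q.

    Zero cells of q would make the divergence infinite whenever p
    occupies them; in that case (and only then) q is regularized by
    adding epsilon (default 1/(10*M_q), a tenth of one count) to every
    cell and renormalizing, so already-overlapping distributions —
    including p == q, which gives exactly 0 — are not distorted.
    K-L is asymmetric: kl(p, q) != kl(q, p) in general.
    """
    parr = p.p if isinstance(p, Distribution1D) else np.asarray(p, dtype=float)
    qarr = q.p if isinstance(q, Distribution1D) else np.asarray(q, dtype=float)
    if parr.shape != qarr.shape:
        raise ValueError("distributions must share binning")
    if epsilon is None:
        m_q = q.M if isinstance(q, Distribution1D) else 1000
        epsilon = 1.0 / (10.0 * m_q)
    if np.any((parr > 0) & (qarr == 0)) and epsilon > 0:
        qreg = qarr + epsilon
        qreg = qreg / qreg.sum()
    else:
        qreg = qarr
    mask = parr > 0
    return float((parr[mask] * np.log(parr[mask] / qreg[mask])).sum())


def _contiguous_splits(m: int, k: int) -> list[slice]:
    bounds = np.linspace(0, m, k + 1).round().astype(int)
    return [slice(bounds[i], bounds[i + 1]) for i in range(k)]


def convergence_check(
    series: list[TorsionSeries] | TorsionSeries,
    n_splits: int = 3,
    threshold: float = 0.2,
    n_bins: int = DEFAULT_BINS,
) -> ConvergenceReport:
    """Classify each torsion's distribution as converged or not.

    The trajectory is cut into ``n_splits`` contiguous equal subsets;
    for every subset pair the K-L divergence is computed in both
    directions and the larger taken (conservative, since K-L is
    asymmetric and no direction is canonical). A torsion is converged
    when the maximum over all pairs is below ``threshold``. Binning
    matches the mutual-information calculation.
    """
    if isinstance(series, TorsionSeries):
        series = [series]
    kl_values: dict[int, tuple] = {}
    converged: dict[int, bool] = {}
    for s in series:
        m = len(s)
        if m < n_splits:
            raise ValueError(f"torsion {s.index}: {m} snapshots < {n_splits} splits")
        parts = [histogram_1d(s.angles[sl], n_bins) for sl in _contiguous_splits(m, n_splits)]
        vals = []
        for i in range(n_splits):
            for j in range(i + 1, n_splits):
                vals.append(max(kl_divergence(parts[i], parts[j]),
                                kl_divergence(parts[j], parts[i])))
        kl_values[s.index] = tuple(vals)
        converged[s.index] = max(vals) < threshold
    return ConvergenceReport(kl_values=kl_values, converged=converged, threshold=threshold)


def permutation_null(
    x: TorsionSeries | np.ndarray,
    y: TorsionSeries | np.ndarray,
    n_rounds: int = 10,
    seed: int = 0,
    n_bins: int = DEFAULT_BINS,
) -> tuple[float, float]:
    """Spurious-correlation bound from independent snapshot resampling.

    Each round draws M indices for x and, independently, M indices for
    y, uniformly with replacement over 1..M, annihilating any true
    coupling; r and MI of the permuted pair measure what finite
    statistics alone can produce. Returns (max |r|, max MI) over rounds.
    """
    ax = x.angles if isinstance(x, TorsionSeries) else np.asarray(x, dtype=float)
    ay = y.angles if isinstance(y, TorsionSeries) else np.asarray(y, dtype=float)
    if ax.size != ay.size:
        raise ValueError("series length mismatch")
    m = ax.size
    if m < 2:
        raise ValueError("need at least 2 snapshots")
    rng = np.random.default_rng(seed)
    max_r, max_mi = 0.0, 0.0
    for _ in range(n_rounds):
        px = ax[rng.integers(0, m, size=m)]
        py = ay[rng.integers(0, m, size=m)]
        r, _ = circular_correlation(px, py)
        mi = mutual_information(px, py, n_bins)
        max_r = max(max_r, abs(r))
        max_mi = max(max_mi, mi)
    return max_r, max_mi


def subset_analysis(
    x: TorsionSeries | np.ndarray,
    y: TorsionSeries | np.ndarray,
    n_subsets: int = 20,
    n_bins: int = DEFAULT_BINS,
) -> SubsetResult:
    """Per-subset (MI, r, joint peaks) over contiguous equal blocks.

    Slowly switching pairs show their coupling in only the few subsets
    that contain a transition; stationary pairs reproduce the full-set
    values in every subset.
    """
    ax = x.angles if isinstance(x, TorsionSeries) else np.asarray(x, dtype=float)
    ay = y.angles if isinstance(y, TorsionSeries) else np.asarray(y, dtype=float)
    m = ax.size
    if n_subsets > m:
        raise ValueError("more subsets than snapshots")
    res = SubsetResult()
    res.full_MI = mutual_information(ax, ay, n_bins)
    res.full_r, _ = circular_correlation(ax, ay)
    for k, sl in enumerate(_contiguous_splits(m, n_subsets)):
        bx, by = ax[sl], ay[sl]
        r, flag = circular_correlation(bx, by)
        mi = mutual_information(bx, by, n_bins)
        peaks = count_joint_peaks(joint_histogram(bx, by, n_bins))
        res.subsets.append(
            {"subset": k, "MI": mi, "r": r, "instability_flag": flag,
             "n_joint_peaks": peaks.n_peaks}
        )
    return res


def thin_snapshots(
    series: list[TorsionSeries],
    stride: int | None = None,
    uniform_count: int | None = None,
) -> list[TorsionSeries]:
    """Thin a trajectory either by stride or to a uniform snapshot count.

    Stride mode keeps indices 0, k, 2k, ...; uniform_count mode keeps n
    evenly spaced indices including the first and last snapshot.
    """
    if (stride is None) == (uniform_count is None):
        raise ValueError("give exactly one of stride or uniform_count")
    m = len(series[0])
    if stride is not None:
        if stride < 1:
            raise ValueError("stride must be >= 1")
        idx = np.arange(0, m, stride)
    else:
        if uniform_count > m:
            raise ValueError("uniform_count exceeds snapshot count")
        idx = np.round(np.linspace(0, m - 1, uniform_count)).astype(int)
    return [
        TorsionSeries(
            index=s.index,
            residue_number=s.residue_number,
            kind=s.kind,
            angles=s.angles[idx],
            ss_class=s.ss_class,
        )
        for s in series
    ]
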