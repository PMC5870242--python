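"""Gaussian-kernel density estimation and mode detection for o/e ratios.

The cleaned sample x_1..x_n is smoothed with the kernel density estimator

    f_h(x) = (1/(n h)) * sum_i K((x - x_i) / h),   K = standard normal pdf,

using the normal-reference bandwidth h = 1.06 * min(sd, IQR/1.34) * n^(-1/5)
(Scott's variation of Silverman's rule of thumb).  Modes are the local
maxima of the estimated density; each mode is assigned the probability
mass between its flanking local minima (grid ends standing in for +-inf).
Post-processing merges modes closer than 0.2 o/e units — too close to
reflect distinct methylation classes — and prunes modes carrying less
than 1% of the mass, which in practice indicates contamination.  A mode
position below 0.75 predicts a presumably methylated sequence
population; at or above 0.75, a presumably non-methylated one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DensityEstimate",
    "Mode",
    "ModeSet",
    "bandwidth_scott",
    "estimate_density",
    "find_modes",
    "assign_masses",
    "postprocess_modes",
    "detect_modes",
    "classify_modes",
    "summary_stats",
    "DEFAULT_MIN_DISTANCE",
    "DEFAULT_MIN_MASS",
    "DEFAULT_THRESHOLD",
    "DEFAULT_GRID_SIZE",
    "STATS_COLUMNS",
    "MAX_REPORTED_MODES",
]

DEFAULT_MIN_DISTANCE = 0.2   # o/e units; closer modes are merged
DEFAULT_MIN_MASS = 0.01      # modes below 1% probability mass are pruned
DEFAULT_THRESHOLD = 0.75     # methylated (<) vs non-methylated (>=)
DEFAULT_GRID_SIZE = 512
WEAK_MASS = 0.1              # display flag: weakly supported mode
MAX_REPORTED_MODES = 10

# grid padding in bandwidths beyond the data range; 4 keeps the truncated
# kernel mass below 1e-4 even for a point mass at the boundary
_GRID_PAD = 4.0


@dataclass
class DensityEstimate:
    """Bandwidth, evaluation grid and density values of a KDE fit."""

    h: float
    grid: np.ndarray
    density: np.ndarray
    n: int

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class Mode:
    """One detected mode with its probability mass and integration bounds."""

    position: float
    mass: float
    left_bound: float
    right_bound: float
    height: float = 0.0
    flags: set[str] = field(default_factory=set)


@dataclass
class ModeSet:
    """Post-processed modes (ascending position) plus bookkeeping."""

    modes: list[Mode]
    n_raw_modes: int
    n_close_merged: int = 0
    density: DensityEstimate | None = None

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position for m in self.modes])

    @property
    def masses(self) -> np.ndarray:
        return np.array([m.mass for m in self.modes])


def _sample_sd_iqr(values: np.ndarray) -> tuple[float, float]:
    sd = float(np.std(values, ddof=1))
    q25, q75 = np.quantile(values, [0.25, 0.75], method="linear")
    return sd, float(q75 - q25)


def bandwidth_scott(values: np.ndarray) -> float:
    """Normal-reference bandwidth 1.06 * min(sd, IQR/1.34) * n^(-1/5).

    ``sd`` is the sample standard deviation (denominator n-1); quantiles
    use linear interpolation.  When the IQR is zero (heavily tied data)
    the spread falls back to the standard deviation alone.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a bandwidth")
    sd, iqr = _sample_sd_iqr(values)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("constant sample: bandwidth would be zero")
    return 1.06 * spread * values.size ** (-1 / 5)


def estimate_density(
    values: np.ndarray,
    h: float | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> DensityEstimate:
    """Evaluate the Gaussian KDE on an equally spaced grid.

    The grid spans the data range padded by a few bandwidths so that
    essentially all kernel mass is covered and the trapezoidal integral
    of the density is 1 to within 1e-3.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot estimate a density from an empty sample")
    if h is None:
        h = bandwidth_scott(values)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid_size < 64:
        raise ValueError("grid_size must be at least 64")
    grid = np.linspace(
        values.min() - _GRID_PAD * h, values.max() + _GRID_PAD * h, grid_size
    )
    # average of standard-normal kernels centered at the data points
    z = (grid[:, None] - values[None, :]) / h
    density = np.exp(-0.5 * z * z).mean(axis=1) / (h * np.sqrt(2.0 * np.pi))
    return DensityEstimate(h=float(h), grid=grid, density=density, n=values.size)


def _fill_sign(diff: np.ndarray) -> np.ndarray:
    """Sign of consecutive differences with zeros carried forward."""
    s = np.sign(diff)
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    return s


def find_modes(de: DensityEstimate) -> tuple[np.ndarray, np.ndarray]:
    """Grid indices of interior local maxima and minima of the density.

    Strict comparisons; plateaus (runs of tied values) collapse to the
    midpoint index of the flat stretch.  Maxima and minima alternate.
    """
    d = de.density
    diff = np.diff(d)
    s = _fill_sign(diff)
    maxima: list[int] = []
    minima: list[int] = []
    # a filled-sign change + -> - marks a maximum, - -> + a minimum
    prev_sign = s[0]
    for i in range(1, s.size):
        if s[i] == 0 or s[i] == prev_sign:
            continue
        if prev_sign != 0:
            # plateau-aware location: midpoint of any tied stretch
            j = i
            while j > 0 and diff[j - 1] == 0:
                j -= 1
            idx = (j + i) // 2
            if prev_sign > 0:
                maxima.append(idx)
            else:
                minima.append(idx)
        prev_sign = s[i]
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def assign_masses(
    de: DensityEstimate, maxima: np.ndarray, minima: np.ndarray
) -> list[Mode]:
    """One mode per maximum; masses integrate the density between the
    flanking local minima (grid ends for the outermost modes) and are
    normalized by the total grid integral so they sum to one.
    """
    grid, dens = de.grid, de.density
    total = de.integral()
    modes: list[Mode] = []
    bounds = np.concatenate(([0], np.sort(minima), [grid.size - 1]))
    for mx in np.sort(maxima):
        left = bounds[bounds <= mx].max()
        right = bounds[bounds >= mx].min()
        mass = float(np.trapezoid(dens[left : right + 1], grid[left : right + 1]))
        modes.append(
            Mode(
                position=float(grid[mx]),
                mass=mass / total,
                left_bound=float(grid[left]),
                right_bound=float(grid[right]),
                height=float(dens[mx]),
            )
        )
    return modes


def _merge_pair(a: Mode, b: Mode) -> Mode:
    """Merge two adjacent modes; the higher-density member keeps the peak."""
    keep = a if a.height >= b.height else b
    return Mode(
        position=keep.position,
        mass=a.mass + b.mass,
        left_bound=min(a.left_bound, b.left_bound),
        right_bound=max(a.right_bound, b.right_bound),
        height=keep.height,
        flags=a.flags | b.flags | {"close"},
    )


def postprocess_modes(
    modes: list[Mode],
    min_distance: float = DEFAULT_MIN_DISTANCE,
    min_mass: float = DEFAULT_MIN_MASS,
) -> ModeSet:
    """Merge close modes, then prune negligible ones.

    Merging is iterative nearest-pair-first: while any two consecutive
    modes are closer than ``min_distance``, the closest such pair is
    merged into one mode at the higher-density member's position, with
    summed mass and united bounds.  Pruning then drops modes with mass
    below ``min_mass``, reassigning each dropped mass to the nearest
    surviving neighbor so the masses remain normalized.  Survivors of a
    merge carry the "close" flag; modes with mass below 0.1 carry "weak".
    """
    if not modes:
        raise ValueError("empty mode list")
    current = sorted(
        (
            Mode(m.position, m.mass, m.left_bound, m.right_bound, m.height,
                 set(m.flags))
            for m in modes
        ),
        key=lambda m: m.position,
    )
    n_raw = len(current)
    n_merged = 0
    while len(current) > 1:
        gaps = [
            current[i + 1].position - current[i].position
            for i in range(len(current) - 1)
        ]
        i = int(np.argmin(gaps))
        if gaps[i] >= min_distance:
            break
        current[i : i + 2] = [_merge_pair(current[i], current[i + 1])]
        n_merged += 1
    while len(current) > 1:
        weakest = min(range(len(current)), key=lambda i: current[i].mass)
        if current[weakest].mass >= min_mass:
            break
        dropped = current.pop(weakest)
        nearest = min(
            range(len(current)),
            key=lambda i: abs(current[i].position - dropped.position),
        )
        current[nearest].mass += dropped.mass
        current[nearest].left_bound = min(
            current[nearest].left_bound, dropped.left_bound
        )
        current[nearest].right_bound = max(
            current[nearest].right_bound, dropped.right_bound
        )
    for m in current:
        if m.mass < WEAK_MASS:
            m.flags.add("weak")
        else:
            m.flags.discard("weak")
    return ModeSet(modes=current, n_raw_modes=n_raw, n_close_merged=n_merged)


def detect_modes(
    values: np.ndarray,
    min_distance: float = DEFAULT_MIN_DISTANCE,
    min_mass: float = DEFAULT_MIN_MASS,
    grid_size: int = DEFAULT_GRID_SIZE,
    h: float | None = None,
) -> ModeSet:
    """Full pipeline on a cleaned sample: KDE, mode finding, masses,
    merge/prune post-processing.  Returns the post-processed mode set
    with the density estimate attached.
    """
    de = estimate_density(values, h=h, grid_size=grid_size)
    maxima, minima = find_modes(de)
    if maxima.size == 0:
        # density maximal at a grid end (monotone estimate); treat the
        # higher end as the single mode spanning the whole grid
        end = int(np.argmax(de.density))
        modes = [
            Mode(
                position=float(de.grid[end]),
                mass=1.0,
                left_bound=float(de.grid[0]),
                right_bound=float(de.grid[-1]),
                height=float(de.density[end]),
            )
        ]
    else:
        modes = assign_masses(de, maxima, minima)
    ms = postprocess_modes(modes, min_distance=min_distance, min_mass=min_mass)
    ms.density = de
    return ms


def classify_modes(
    ms: ModeSet, threshold: float = DEFAULT_THRESHOLD
) -> list[str]:
    """Label each mode "methylated" (position < threshold) or
    "non-methylated" (position >= threshold)."""
    return [
        "methylated" if m.position < threshold else "non-methylated"
        for m in ms.modes
    ]


STATS_COLUMNS = (
    "Name",
    "Number of modes",
    "Number of modes (5% excluded)",
    "Number of modes (10% excluded)",
    "Skewness",
    "Mode skewness",
    "Nonparametric skew",
    "Q50 skewness",
    "Absolute Q50 mode skewness",
    "Absolute Q80 mode skewness",
    *[f"Peak {i}" for i in range(1, MAX_REPORTED_MODES + 1)],
    *[f"Probability Mass {i}" for i in range(1, MAX_REPORTED_MODES + 1)],
    "Warning close modes",
    "Number close modes",
    "Modes (close modes excluded)",
    "SD",
    "IQR 80",
    "IQR 90",
    "Total number of sequences",
)


def summary_stats(values: np.ndarray, ms: ModeSet, name: str = "sample") -> dict:
    """Summary-statistics record for the mode table.

    Includes the mode counts at the 5%/10% mass cutoffs, four skewness
    measures (moment skewness, Pearson's first coefficient, nonparametric
    skew, Bowley's quartile skewness), two mode-anchored absolute skews,
    per-mode positions and masses (up to 10), and robust spread measures.
    ``Mo`` is the position of the highest-mass mode.
    """
    values = np.asarray(values, dtype=float)
    mu = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    q = lambda p: float(np.quantile(values, p, method="linear"))
    q1, q2, q3 = q(0.25), q(0.5), q(0.75)
    mo = ms.modes[int(np.argmax(ms.masses))].position
    n_modes = len(ms.modes)
    n_close = sum("close" in m.flags for m in ms.modes)
    row: dict = {
        "Name": name,
        "Number of modes": n_modes,
        "Number of modes (5% excluded)": int(np.sum(ms.masses >= 0.05)),
        "Number of modes (10% excluded)": int(np.sum(ms.masses >= 0.10)),
        "Skewness": float(stats.skew(values, bias=True)),
        "Mode skewness": (mu - mo) / sd,
        "Nonparametric skew": (mu - q2) / sd,
        "Q50 skewness": (q3 + q1 - 2 * q2) / (q3 - q1) if q3 > q1 else 0.0,
        "Absolute Q50 mode skewness": (q3 + q1) / 2 - mo,
        "Absolute Q80 mode skewness": (q(0.9) + q(0.1)) / 2 - mo,
        "Warning close modes": int(n_close > 0),
        "Number close modes": n_close,
        "Modes (close modes excluded)": n_modes - n_close,
        "SD": sd,
        "IQR 80": q(0.9) - q(0.1),
        "IQR 90": q(0.95) - q(0.05),
        "Total number of sequences": int(values.size),
    }
    for i in range(MAX_REPORTED_MODES):
        row[f"Peak {i + 1}"] = (
            ms.modes[i].position if i < n_modes else None
        )
        row[f"Probability Mass {i + 1}"] = (
            ms.modes[i].mass if i < n_modes else None
        )
    return {c: row[c] for c in STATS_COLUMNS}
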