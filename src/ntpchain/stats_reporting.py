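"""Statistics layer: decorrelated sampling, pooled t-tests, Gaussian fits
of dihedral histograms, and normalized conformational heat maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from scipy.optimize import least_squares
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "DecorrelationResult",
    "TTestResult",
    "GaussianTerm",
    "GaussianFit",
    "HeatMap",
    "FitFailureError",
    "autocorr_decimate",
    "two_sample_t",
    "fit_gaussians",
    "build_heatmap",
    "plot_heatmap",
    "plot_histogram_fit",
]


class FitFailureError(RuntimeError):
    """Gaussian fit did not converge; message carries diagnostics."""


# ---------------------------------------------------------------------------
# decorrelation
# ---------------------------------------------------------------------------

@dataclass
class DecorrelationResult:
    acf: np.ndarray              # ACF by lag, acf[0] == 1
    stride: int                  # decimation stride N (frames)
    criterion: str               # '1/e' or 'integrated'
    sample_indices: np.ndarray   # extracted decorrelated frame indices
    sample: np.ndarray           # series values at those indices

    @property
    def correlation_time(self) -> float:
        """Integrated correlation time (frames), truncated at the first
        non-positive ACF value."""
        neg = np.nonzero(self.acf[1:] <= 0)[0]
        stop = neg[0] + 1 if len(neg) else len(self.acf)
        return float(1.0 + 2.0 * np.sum(self.acf[1:stop]))


def autocorr_decimate(
    series,
    mask=None,
    criterion: str = "1/e",
    max_lag: Optional[int] = None,
) -> DecorrelationResult:
    """Autocorrelation-based extraction of decorrelated frames.

    The ACF is the mean-removed normalized autocovariance.  The stride N is
    the smallest lag with ACF < 1/e (default criterion) or the ceiling of
    the integrated correlation time (``criterion='integrated'``).  When a
    boolean ``mask`` is given (e.g. 'at least one cation bound'), only
    masked frames are eligible, and consecutive picks are at least N frames
    apart.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("series too short for autocorrelation")
    if np.std(x) == 0:
        raise ValueError("constant series: autocorrelation undefined")
    nlags = min(n - 1, max_lag if max_lag is not None else n // 2)
    acf = _sm_acf(x, nlags=nlags, fft=True)

    if criterion == "1/e":
        below = np.nonzero(acf < 1.0 / np.e)[0]
        stride = int(below[0]) if len(below) else nlags
    elif criterion == "integrated":
        neg = np.nonzero(acf[1:] <= 0)[0]
        stop = neg[0] + 1 if len(neg) else len(acf)
        stride = int(np.ceil(1.0 + 2.0 * np.sum(acf[1:stop])))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    stride = max(stride, 1)

    if mask is None:
        eligible = np.arange(n)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != x.shape:
            raise ValueError("mask must match series length")
        eligible = np.nonzero(mask)[0]
        if len(eligible) == 0:
            raise ValueError("mask excludes every frame: empty sample")
    picks = []
    last = -stride
    for i in eligible:
        if i - last >= stride:
            picks.append(i)
            last = i
    picks = np.asarray(picks, dtype=int)
    return DecorrelationResult(acf=acf, stride=stride, criterion=criterion,
                               sample_indices=picks, sample=x[picks])


# ---------------------------------------------------------------------------
# pooled-variance two-sample t-test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    dof: int
    p: float
    reject: bool  # at the 5% level
    alpha: float = 0.05


def two_sample_t(sample_a, sample_b, alpha: float = 0.05) -> TTestResult:
    """Two-sided two-sample t-test with pooled standard deviation.

    Under the null of equal means (equal unknown variances) the statistic
    follows Student's t with n + m - 2 degrees of freedom.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n, m = len(a), len(b)
    if n < 2 or m < 2:
        raise ValueError("both samples need at least two observations")
    dof = n + m - 2
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    sp2 = ((n - 1) * va + (m - 1) * vb) / dof
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, dof, 1.0, False, alpha)
        t = np.inf if diff > 0 else -np.inf
        return TTestResult(float(t), dof, 0.0, True, alpha)
    t = diff / np.sqrt(sp2 * (1.0 / n + 1.0 / m))
    p = 2.0 * sps.t.sf(abs(t), dof)
    return TTestResult(float(t), int(dof), float(p), bool(p < alpha), alpha)


# ---------------------------------------------------------------------------
# Gaussian fits of dihedral histograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianTerm:
    weight: float
    centroid: float  # degrees
    sigma: float     # degrees


@dataclass
class GaussianFit:
    terms: List[GaussianTerm]  # sorted by descending weight
    rss: float
    bin_centers: np.ndarray
    bin_density: np.ndarray

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def main(self) -> GaussianTerm:
        """The dominant (highest-weight) peak."""
        return self.terms[0]

    def evaluate(self, x):
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x)
        for t in self.terms:
            y = y + t.weight * np.exp(-0.5 * ((x - t.centroid) / t.sigma) ** 2)
        return y


def _histogram(angles, bin_width, hist_range):
    angles = np.asarray(angles, dtype=float)
    if hist_range is None:
        lo = np.floor(angles.min() / bin_width) * bin_width
        hi = np.ceil(angles.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = hist_range
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    density, edges = np.histogram(angles, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def fit_gaussians(
    angles=None,
    n_terms: int = 1,
    bin_width: float = 2.0,
    hist_range: Optional[Tuple[float, float]] = None,
    histogram: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    restarts: int = 5,
    seed: int = 0,
) -> GaussianFit:
    """Least-squares fit of a 1- or 2-term Gaussian to an angle histogram.

    Accepts raw angles (binned at ``bin_width`` degrees) or a prebuilt
    ``histogram=(centers, density)``.  Multi-start (deterministic seed) to
    avoid local minima in 2-term fits; the dominant peak is reported first.
    """
    if n_terms not in (1, 2):
        raise ValueError("n_terms must be 1 or 2")
    if histogram is not None:
        centers, density = (np.asarray(v, dtype=float) for v in histogram)
    elif angles is not None:
        centers, density = _histogram(angles, bin_width, hist_range)
    else:
        raise ValueError("need raw angles or a histogram")
    occupied = np.nonzero(density > 0)[0]
    if len(occupied) < 5 * n_terms:
        raise FitFailureError(
            f"{len(occupied)} occupied bins; need >= {5 * n_terms} "
            f"for a {n_terms}-term fit"
        )

    def model(p, x):
        y = np.zeros_like(x)
        for k in range(n_terms):
            w, c, s = p[3 * k:3 * k + 3]
            y = y + w * np.exp(-0.5 * ((x - c) / s) ** 2)
        return y

    def resid(p):
        return model(p, centers) - density

    # initial guesses: dominant bin, then the strongest distant bin
    rng = np.random.default_rng(seed)
    i_max = int(np.argmax(density))
    spread = max((centers[occupied][-1] - centers[occupied][0]) / 4.0, bin_width)
    inits = []
    base = [density[i_max], centers[i_max], spread]
    if n_terms == 2:
        far = np.abs(centers - centers[i_max]) > 2 * spread
        if np.any(far & (density > 0)):
            j = int(np.argmax(np.where(far, density, -1.0)))
        else:
            j = int(np.argmax(np.where(np.arange(len(centers)) != i_max,
                                       density, -1.0)))
        base = base + [density[j], centers[j], spread]
    inits.append(np.array(base))
    for _ in range(max(restarts - 1, 0)):
        jit = inits[0] * (1.0 + 0.3 * rng.standard_normal(len(base)))
        jit[0::3] = np.abs(jit[0::3]) + 1e-6
        jit[2::3] = np.abs(jit[2::3]) + bin_width / 4.0
        inits.append(jit)

    lb = [0.0, -np.inf, bin_width / 10.0] * n_terms
    ub = [np.inf, np.inf, np.inf] * n_terms
    best = None
    failures = []
    for x0 in inits:
        x0 = np.clip(x0, lb, None)
        sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                            xtol=1e-12, ftol=1e-12, max_nfev=2000)
        rss = float(np.sum(sol.fun ** 2))
        if not sol.success:
            failures.append(sol.message)
            continue
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise FitFailureError(
            "no restart converged: " + "; ".join(failures[:3])
        )
    rss, p = best
    terms = sorted(
        (GaussianTerm(float(p[3 * k]), float(p[3 * k + 1]), float(abs(p[3 * k + 2])))
         for k in range(n_terms)),
        key=lambda t: -t.weight,
    )
    return GaussianFit(terms=list(terms), rss=rss,
                       bin_centers=centers, bin_density=density)


# ---------------------------------------------------------------------------
# heat maps
# ---------------------------------------------------------------------------

@dataclass
class HeatMap:
    grid: np.ndarray       # normalized frequency, sums to 1 over occupied cells
    x_edges: np.ndarray    # d_pa_pg (Angstrom)
    y_edges: np.ndarray    # theta_bridge (degrees)
    overlays: Dict[str, np.ndarray] = field(default_factory=dict)

    def overlay_hull(self, name: str) -> np.ndarray:
        """Convex-hull vertices (closed polygon) of an overlay point set."""
        from scipy.spatial import ConvexHull

        pts = np.asarray(self.overlays[name], dtype=float)
        if len(pts) < 3:
            return pts
        hull = ConvexHull(pts)
        v = pts[hull.vertices]
        return np.vstack([v, v[:1]])


def build_heatmap(
    d_values,
    theta_values,
    x_edges=None,
    y_edges=None,
    bins=(40, 40),
    filter_mask=None,
    overlays: Optional[Dict[str, np.ndarray]] = None,
) -> HeatMap:
    """2D normalized-frequency map over (d_pa_pg, theta_bridge).

    ``filter_mask`` implements conditioning (e.g. 'at least one cation
    within 4 A of the chain'); overlay point sets (crystal-structure
    analog classes) are stored for hull outlines.
    """
    d = np.asarray(d_values, dtype=float)
    th = np.asarray(theta_values, dtype=float)
    if filter_mask is not None:
        m = np.asarray(filter_mask, dtype=bool)
        d, th = d[m], th[m]
    if x_edges is None or y_edges is None:
        counts, xe, ye = np.histogram2d(d, th, bins=bins)
    else:
        counts, xe, ye = np.histogram2d(d, th, bins=(x_edges, y_edges))
        inside = np.sum(counts)
        if len(d) and inside < len(d):
            raise ValueError(
                f"grid does not cover the data: {len(d) - int(inside)} "
                "points fall outside"
            )
    total = counts.sum()
    grid = counts / total if total > 0 else counts
    return HeatMap(grid=grid, x_edges=xe, y_edges=ye,
                   overlays={k: np.asarray(v, float)
                             for k, v in (overlays or {}).items()})


# ---------------------------------------------------------------------------
# plotting (Agg-safe)
# ---------------------------------------------------------------------------

def plot_heatmap(hm: HeatMap, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.pcolormesh(hm.x_edges, hm.y_edges, hm.grid.T, cmap="Greys")
    colors = {"transition_state": "magenta", "non_hydrolyzable": "blue"}
    for name, pts in hm.overlays.items():
        if len(pts) == 0:
            continue
        hull = hm.overlay_hull(name)
        ax.plot(hull[:, 0], hull[:, 1], linestyle="--",
                color=colors.get(name, "red"), label=name)
    ax.set_xlabel("PA-PG distance (A)")
    ax.set_ylabel("PB-O3B-PG angle (deg)")
    if title:
        ax.set_title(title)
    if hm.overlays:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_histogram_fit(fit: GaussianFit, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(fit.bin_centers, fit.bin_density, lw=0.8, label="histogram")
    xs = np.linspace(fit.bin_centers[0], fit.bin_centers[-1], 400)
    ax.plot(xs, fit.evaluate(xs), lw=1.6, label="fit")
    ax.axvline(fit.main.centroid, linestyle="--", color="k", lw=0.8)
    ax.set_xlabel("dihedral (deg)")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
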