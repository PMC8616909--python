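"""Comparative and thermodynamic metrics on top of the multifractal curves.

The structure distance is the root-mean-square gap between two
generalized-dimension curves over a q range; the asymmetry is the log ratio
of the spectrum's left and right half-widths (positive: dense hub-dominated
"clump" structure, negative: sparse chain-dominated "thorn" structure); the
specific heat ``C(q) = d(alpha)/dq`` flags phase-transition-like changes of
the dominant structural mechanism where |C| peaks.

``C`` is kept with its literal sign (non-positive for well-behaved spectra);
peak detection runs on |C| so it is insensitive to that sign convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .graph import Network, largest_component
from .multifractal import (
    AnalysisConfig,
    GeneralizedDimension,
    MultifractalSpectrum,
    NMFAResult,
    QGrid,
    analyze,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SpecificHeatCurve",
    "PhaseTransition",
    "StructureDistanceMatrix",
    "structure_distance",
    "asymmetry",
    "specific_heat",
    "detect_phase_transitions",
    "summarize",
    "structure_distance_matrix",
    "deletion_experiment",
]

_EPS = 1e-12
DEGENERATE_WIDTH = 1e-3  # below this the spectrum counts as a single point


@dataclass(frozen=True)
class PhaseTransition:
    q_c: float
    magnitude: float  # |C| at the peak

    @property
    def mechanism(self) -> str:
        """"clump" when dense structure drives the transition (q_c > 0)."""
        return "clump" if self.q_c > 0 else "thorn"


@dataclass(frozen=True)
class SpecificHeatCurve:
    qgrid: QGrid
    C: np.ndarray


@dataclass(frozen=True)
class StructureDistanceMatrix:
    names: tuple[str, ...]
    matrix: np.ndarray
    q_range: tuple[float, float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.names, columns=self.names)


def _restrict(q: np.ndarray, q_range, exclude_zero: bool) -> np.ndarray:
    mask = np.ones(len(q), dtype=bool)
    if q_range is not None:
        lo, hi = q_range
        mask &= (q >= lo - _EPS) & (q <= hi + _EPS)
    if exclude_zero:
        mask &= q != 0
    if mask.sum() < 2:
        raise ValueError("q range leaves fewer than 2 grid points")
    return mask


def structure_distance(
    D1: GeneralizedDimension,
    D2: GeneralizedDimension,
    q_range: tuple[float, float] | None = None,
    exclude_zero: bool = False,
) -> float:
    """RMS difference of two D(q) curves over a shared q range.

    The squared gap is integrated by the trapezoidal rule and normalized by
    the range length, i.e. ``sqrt(mean((D1 - D2)^2))`` in the continuum
    limit.  A pseudometric: nonnegative, symmetric, zero on identical curves.
    """
    q1, q2 = D1.qgrid.values, D2.qgrid.values
    if len(q1) != len(q2) or not np.allclose(q1, q2):
        raise ValueError("curves are defined on different q grids")
    mask = _restrict(q1, q_range, exclude_zero)
    q = q1[mask]
    gap2 = (D1.D[mask] - D2.D[mask]) ** 2
    integral = np.trapezoid(gap2, q)
    return float(np.sqrt(integral / (q[-1] - q[0])))


def asymmetry(spec: MultifractalSpectrum,
              degenerate_width: float = DEGENERATE_WIDTH) -> float:
    """Log ratio of the spectrum's half-widths: ln((a0-amin)/(amax-a0)).

    Degenerate (single-point) spectra return 0 by convention.
    """
    a0, amin, amax = spec.alpha0, spec.alpha_min, spec.alpha_max
    if abs(amax - amin) < degenerate_width:
        return 0.0
    if amax < amin:
        raise ValueError(
            f"inconsistent spectrum: alpha_max={amax} < alpha_min={amin}"
        )
    tol = 1e-6 * max(1.0, abs(amax - amin))
    if a0 < amin - tol or a0 > amax + tol:
        raise ValueError(
            f"inconsistent spectrum: alpha0={a0} outside "
            f"[{amin}, {amax}]"
        )
    left = max(a0 - amin, 0.0)
    right = max(amax - a0, 0.0)
    if left <= 0:
        return -np.inf
    if right <= 0:
        return np.inf
    return float(np.log(left / right))


def specific_heat(spec: MultifractalSpectrum, qgrid: QGrid | None = None,
                  smooth_window: int = 0) -> SpecificHeatCurve:
    """``C(q) = d(alpha)/dq`` by central differences (literal sign kept)."""
    if qgrid is None:
        qgrid = spec.qgrid
    alpha = spec.alpha
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(alpha, pad, mode="edge")
        alpha = np.convolve(padded, kernel, mode="valid")[: len(spec.alpha)]
    C = np.gradient(alpha, qgrid.values)
    return SpecificHeatCurve(qgrid, C)


def detect_phase_transitions(
    heat: SpecificHeatCurve,
    prominence: float = 0.2,
    min_separation: float = 1.0,
) -> list[PhaseTransition]:
    """Local maxima of |C(q)| above a prominence threshold.

    ``prominence`` is a fraction of max |C|; ``min_separation`` is the
    minimum spacing between reported peaks, in q units.  Returned in
    increasing q.
    """
    absC = np.abs(heat.C)
    top = absC.max()
    if top < _EPS:
        return []
    q = heat.qgrid.values
    dq = float(np.median(np.diff(q)))
    idx, props = find_peaks(
        absC,
        prominence=prominence * top,
        distance=max(1, int(round(min_separation / dq))),
    )
    return [PhaseTransition(float(q[i]), float(absC[i])) for i in idx]


def summarize(spec: MultifractalSpectrum) -> tuple[float, float]:
    """(complexity, heterogeneity) = (alpha0, spectrum width)."""
    return spec.alpha0, spec.width


def structure_distance_matrix(
    results: list[NMFAResult] | list[GeneralizedDimension],
    q_range: tuple[float, float] | None = None,
    names: list[str] | None = None,
    exclude_zero: bool = False,
) -> StructureDistanceMatrix:
    """All pairwise structure distances between analysis results."""
    dims = [r.dimension if isinstance(r, NMFAResult) else r for r in results]
    n = len(dims)
    if names is None:
        names = [f"net{i}" for i in range(n)]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dval = structure_distance(dims[i], dims[j], q_range, exclude_zero)
            mat[i, j] = mat[j, i] = dval
    q = dims[0].qgrid.values
    mask = _restrict(q, q_range, exclude_zero)
    return StructureDistanceMatrix(
        tuple(names), mat, (float(q[mask][0]), float(q[mask][-1]))
    )


def deletion_experiment(
    net: Network,
    order: str = "descending",
    steps: int = 10,
    remove_fraction: float = 0.5,
    config: AnalysisConfig | None = None,
    q_range: tuple[float, float] | None = None,
):
    """Cumulative edge deletion ranked by betweenness, tracking distance.

    Edge importance (betweenness centrality) is computed once on the
    original network; edges are then removed cumulatively in ``order``
    ("descending" removes the most important first).  After each of
    ``steps`` equal batches the structure distance between the current
    largest component and the original network is recorded.

    Returns a DataFrame with columns ``n_removed`` and ``distance``; the
    first row is the unmodified network at distance 0.
    """
    import networkx as nx
    import pandas as pd

    if order not in ("ascending", "descending"):
        raise ValueError("order must be 'ascending' or 'descending'")
    if config is None:
        config = AnalysisConfig()
    n_remove = int(round(remove_fraction * net.n_edges))
    if not 0 < n_remove < net.n_edges:
        raise ValueError("remove_fraction leaves no experiment to run")
    if steps < 1 or steps > n_remove:
        raise ValueError("steps must be in [1, edges removed]")

    g = net.to_networkx()
    ebc = nx.edge_betweenness_centrality(g, weight=None)
    ranked = sorted(ebc, key=lambda e: ebc[e], reverse=(order == "descending"))
    ranked = ranked[:n_remove]

    baseline = analyze(net, config)
    rows = [(0, 0.0)]
    bounds = np.linspace(0, n_remove, steps + 1).round().astype(int)
    current = net
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi == lo:
            continue
        current = current.drop_edges(ranked[lo:hi])
        piece = largest_component(current)
        result = analyze(piece, config)
        dist = structure_distance(
            result.dimension, baseline.dimension, q_range
        )
        rows.append((int(hi), dist))
    return pd.DataFrame(rows, columns=["n_removed", "distance"])
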