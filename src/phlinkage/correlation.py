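"""Protonation correlations, threshold networks and correlation times.

Pairwise coupling between titratable sites shows up as correlation between
their binary protonation time series.  For binary variables the Pearson
coefficient equals the phi coefficient; pairs where either site barely
fluctuates (variance below ``VARIANCE_FLOOR``) are *undefined* — masked, not
set to zero.  Thresholding |correlation| per pH yields an edge network whose
cross-compartment edges flag lumen-stroma coupling.

The protonation correlation time of a site is the integrated autocorrelation
time of its binary series,

    tau = 1/2 + sum_{t >= 1} C(t)      [frames],

with C(t) the normalized fluctuation autocorrelation averaged over replicates
and the sum truncated at the first nonpositive lag (initial positive sequence
truncation).  White noise gives tau = 1/2; slow exchangers give large tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .ensemble import ProtonationEnsemble, ProtonationTrajectory

VARIANCE_FLOOR = 1e-6
DEFAULT_EDGE_THRESHOLD = 0.3


@dataclass
class CorrelationMap:
    """Symmetric per-pH site-site correlation matrix with a validity mask."""

    pH: float
    matrix: np.ndarray           # NaN where undefined
    defined: np.ndarray          # boolean mask, symmetric
    n_samples: int

    def __post_init__(self) -> None:
        vals = self.matrix[self.defined]
        if vals.size and (np.nanmin(vals) < -1 - 1e-9 or np.nanmax(vals) > 1 + 1e-9):
            raise ValueError("defined correlations must lie in [-1, 1]")


@dataclass
class CorrelationNetwork:
    """Thresholded per-pH edge list over the site graph."""

    threshold: float
    edges: pd.DataFrame          # site_i, site_j, pH, correlation, sign, cross_compartment

    def at(self, pH: float) -> pd.DataFrame:
        return self.edges[np.isclose(self.edges["pH"], pH)]

    def to_networkx(self, pH: float) -> nx.Graph:
        g = nx.Graph()
        for row in self.at(pH).itertuples():
            g.add_edge(row.site_i, row.site_j, correlation=row.correlation,
                       sign=row.sign, cross_compartment=row.cross_compartment)
        return g


@dataclass
class CorrelationTime:
    """Integrated autocorrelation time of one site's protonation series."""

    site: str
    pH: float
    tau_frames: float            # NaN when undefined
    cutoff_lag: int
    n_replicates: int
    defined: bool
    reason: str = ""
    tau_scaled: float | None = None   # tau * frame_spacing if spacing numeric


def pairwise_correlation(
    ensemble: ProtonationEnsemble,
    pH: float,
    pooling: str = "pooled",
) -> CorrelationMap:
    """Pearson (phi) correlation map of protonation states at one pH.

    ``pooling="pooled"`` concatenates frames across replicates before
    correlating (default); ``"per-replicate-mean"`` averages the per-replicate
    correlation maps, which is robust against single trapped replicates
    inflating pooled correlations.
    """
    if pooling not in ("pooled", "per-replicate-mean"):
        raise ValueError(f"unknown pooling {pooling!r}")
    if pooling == "pooled":
        x = ensemble.pooled_states(pH).astype(float)
        matrix, defined = _masked_corrcoef(x)
        n_samples = x.shape[0]
    else:
        maps = []
        n_samples = 0
        for t in ensemble.at(pH):
            m, _ = _masked_corrcoef(t.states.astype(float))
            maps.append(m)
            n_samples += t.n_frames
        with np.errstate(invalid="ignore"):
            matrix = np.nanmean(np.stack(maps), axis=0)
        defined = np.isfinite(matrix)
    return CorrelationMap(pH=float(pH), matrix=matrix, defined=defined,
                          n_samples=n_samples)


def _masked_corrcoef(x: np.ndarray):
    var = x.var(axis=0)
    ok = var >= VARIANCE_FLOOR
    n = x.shape[1]
    matrix = np.full((n, n), np.nan)
    if ok.any():
        sub = np.corrcoef(x[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        matrix[np.ix_(ok, ok)] = np.clip(sub, -1.0, 1.0)
    defined = np.outer(ok, ok)
    return matrix, defined


def build_network(
    maps: CorrelationMap | list[CorrelationMap],
    sites: pd.DataFrame,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> CorrelationNetwork:
    """Threshold correlation maps into a per-pH edge network.

    Edges are defined site pairs with |correlation| >= threshold; each edge
    records its sign and whether it bridges the lumenal and stromal
    compartments.  Undefined (masked) pairs never contribute edges.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if isinstance(maps, CorrelationMap):
        maps = [maps]
    ids = sites["site_id"].tolist()
    comp = sites["compartment"].tolist()
    rows = []
    for cmap in maps:
        mat, ok = cmap.matrix, cmap.defined
        n = mat.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if ok[i, j] and abs(mat[i, j]) >= threshold:
                    rows.append({
                        "site_i": ids[i], "site_j": ids[j], "pH": cmap.pH,
                        "correlation": float(mat[i, j]),
                        "sign": int(np.sign(mat[i, j])),
                        "cross_compartment": comp[i] != comp[j],
                    })
    edges = pd.DataFrame(rows, columns=["site_i", "site_j", "pH", "correlation",
                                        "sign", "cross_compartment"])
    return CorrelationNetwork(threshold=threshold, edges=edges)


def _normalized_acf(x: np.ndarray) -> np.ndarray:
    """Biased-normalization fluctuation ACF via FFT; acf[0] = 1."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = x.size
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n] / n
    return acov / acov[0]


def correlation_time(
    trajectories: ProtonationTrajectory | list[ProtonationTrajectory],
    site: int,
    site_id: str | None = None,
) -> CorrelationTime:
    """Integrated protonation correlation time of one site (column index).

    Replicate trajectories are averaged at the level of the normalized ACF;
    replicates with zero variance at the site are dropped.  If no replicate
    fluctuates, the estimate is undefined (NaN) with a reason.
    """
    if isinstance(trajectories, ProtonationTrajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise ValueError("need at least one trajectory")
    ph = trajectories[0].pH
    name = site_id if site_id is not None else f"site{site}"
    if min(t.n_frames for t in trajectories) < 10:
        raise ValueError("correlation time needs trajectories of >= 10 frames")

    acfs = []
    for t in trajectories:
        x = t.states[:, site]
        if x.var() < VARIANCE_FLOOR:
            continue
        acfs.append(_normalized_acf(x))
    if not acfs:
        return CorrelationTime(site=name, pH=ph, tau_frames=np.nan, cutoff_lag=0,
                               n_replicates=len(trajectories), defined=False,
                               reason="site has zero protonation variance")
    n_min = min(a.size for a in acfs)
    acf = np.mean([a[:n_min] for a in acfs], axis=0)
    nonpos = np.nonzero(acf[1:] <= 0)[0]
    cutoff = int(nonpos[0] + 1) if nonpos.size else n_min
    tau = 0.5 + float(acf[1:cutoff].sum())

    spacing = trajectories[0].frame_spacing
    scaled = tau * spacing if isinstance(spacing, (int, float)) else None
    return CorrelationTime(site=name, pH=ph, tau_frames=tau, cutoff_lag=cutoff,
                           n_replicates=len(acfs), defined=True, tau_scaled=scaled)


def ensemble_correlation_times(ensemble: ProtonationEnsemble, pH: float) -> list[CorrelationTime]:
    """Correlation time of every site at one pH, replicate-averaged."""
    trs = ensemble.at(pH)
    return [correlation_time(trs, i, site_id=sid)
            for i, sid in enumerate(ensemble.sites["site_id"])]
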