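"""Titration curves with bootstrap confidence bands and Hill fits.

Per-residue and global (summed) titration curves are computed as
time-and-replicate averages of the binary protonation states.  Uncertainty
bands are 68% confidence intervals from a replicate-level bootstrap: whole
replicates are resampled with replacement, never individual frames, because
frames within a replicate are autocorrelated (protonation correlation times
can span a large fraction of a trajectory) while replicates are independent.

Curves are fitted to the Hill equation

    <x>(pH) = 1 / (1 + 10^(h * (pH - pKa)))

whose midpoint is the fitted pKa and whose slope parameter h measures
cooperativity of proton binding (h < 1 anticooperative, h > 1 cooperative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .ensemble import ProtonationEnsemble

DEFAULT_N_BOOT = 1000
CI_PERCENTILES = (16.0, 84.0)        # central 68%


@dataclass
class TitrationCurve:
    """Mean protonation vs pH with a 68% CI band."""

    subject: str
    pH: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_replicates: np.ndarray
    degenerate_ci: bool = False      # single replicate: zero-width band

    def __post_init__(self) -> None:
        for name in ("pH", "mean", "ci_lo", "ci_hi", "n_replicates"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if not (np.all(self.ci_lo <= self.mean + 1e-12)
                and np.all(self.mean <= self.ci_hi + 1e-12)):
            raise ValueError("CI band must contain the mean at every pH")

    @property
    def half_width(self) -> np.ndarray:
        return (self.ci_hi - self.ci_lo) / 2.0


@dataclass
class HillFit:
    """Hill-equation fit of a per-site titration curve."""

    pka: float
    hill_h: float
    pka_se: float
    hill_se: float
    converged: bool
    low_confidence: bool = False
    reason: str = ""

    def predict(self, pH) -> np.ndarray:
        return hill_curve(np.asarray(pH, float), self.pka, self.hill_h)


def hill_curve(pH, pka, h):
    return 1.0 / (1.0 + 10.0 ** (h * (np.asarray(pH, float) - pka)))


def bootstrap_ci(replicate_stats, n_boot: int = DEFAULT_N_BOOT, seed: int = 0):
    """Percentile 68% CI of the replicate-mean statistic.

    ``replicate_stats`` has replicates on axis 0 (any trailing shape).
    Returns ``(lo, hi, degenerate)`` where ``degenerate`` flags the
    single-replicate case (zero-width interval).
    """
    stats = np.asarray(replicate_stats, dtype=float)
    n_reps = stats.shape[0]
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if n_reps == 1:
        return stats[0].copy(), stats[0].copy(), True
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_reps, size=(n_boot, n_reps))
    resampled = stats[idx].mean(axis=1)          # (n_boot, ...)
    lo, hi = np.percentile(resampled, CI_PERCENTILES, axis=0)
    # percentile bands can narrowly exclude the point estimate; widen to include it
    point = stats.mean(axis=0)
    return np.minimum(lo, point), np.maximum(hi, point), False


def _curve_from_replicate_stats(subject, pH_grid, rep_stats_per_ph, pooled_means,
                                pooling, n_boot, seed):
    means, lo, hi, n_reps = [], [], [], []
    degenerate = False
    for k, ph in enumerate(pH_grid):
        stats = rep_stats_per_ph[k]
        point = pooled_means[k] if pooling == "pooled" else stats.mean()
        l, h, deg = bootstrap_ci(stats, n_boot=n_boot, seed=seed + k)
        degenerate |= deg
        means.append(point)
        lo.append(min(float(l), point))
        hi.append(max(float(h), point))
        n_reps.append(stats.shape[0])
    return TitrationCurve(subject=subject, pH=np.asarray(pH_grid, float),
                          mean=np.array(means), ci_lo=np.array(lo),
                          ci_hi=np.array(hi), n_replicates=np.array(n_reps),
                          degenerate_ci=degenerate)


def residue_curve(
    ensemble: ProtonationEnsemble,
    site: str,
    chain_policy: str = "average-chains",
    chain: str | None = None,
    pooling: str = "pooled",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> TitrationCurve:
    """Titration curve of one residue.

    ``chain_policy="average-chains"`` returns the arithmetic mean of the
    residue's curves over all chains carrying it (the dimer convention);
    ``"single-chain"`` requires ``chain`` when the label spans several chains.
    """
    if chain_policy not in ("average-chains", "single-chain"):
        raise ValueError(f"unknown chain_policy {chain_policy!r}")
    chains = sorted(ensemble.sites.loc[ensemble.sites["label"] == site, "chain"])
    if not chains:
        raise KeyError(f"site {site!r} not in ensemble")
    if chain_policy == "single-chain":
        if chain is None and len(chains) > 1:
            raise ValueError(f"site {site!r} present in chains {chains}; pass chain=")
        cols = [ensemble.site_index(site, chain if chain is not None else chains[0])]
        subject = f"{site}:{chain or chains[0]}"
    else:
        if ensemble.system == "dimer" and len(chains) < 2:
            raise ValueError(
                f"average-chains requires {site!r} in both dimer chains; "
                f"found only {chains}")
        cols = [ensemble.site_index(site, c) for c in chains]
        subject = f"{site}:mean({','.join(chains)})"

    grid = ensemble.pH_grid
    rep_stats = [ensemble.replicate_site_means(ph)[:, cols].mean(axis=1)
                 for ph in grid]
    pooled = [float(ensemble.pooled_site_means(ph)[cols].mean()) for ph in grid]
    return _curve_from_replicate_stats(subject, grid, rep_stats, pooled,
                                       pooling, n_boot, seed)


def global_curve(
    ensemble: ProtonationEnsemble,
    subset: dict | None = None,
    stoichiometry_factor: float = 1.0,
    pooling: str = "pooled",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> TitrationCurve:
    """Summed protonation curve over a site subset, scaled by stoichiometry.

    ``subset`` is a filter dict accepted by
    :meth:`ProtonationEnsemble.subset_indices` (e.g. ``{"compartment":
    "lumenal"}``).  ``stoichiometry_factor=2`` on a monomer matches dimer
    stoichiometry.  The global curve is exactly the scaled sum of the
    per-site curves computed on the same ensemble.
    """
    if stoichiometry_factor <= 0:
        raise ValueError("stoichiometry_factor must be positive")
    idx = ensemble.subset_indices(**(subset or {}))
    if idx.size == 0:
        raise ValueError(f"site subset {subset!r} is empty")
    desc = "all" if not subset else ",".join(f"{k}={v}" for k, v in subset.items())
    subject = f"global[{desc}]x{stoichiometry_factor:g}"

    grid = ensemble.pH_grid
    rep_stats = [stoichiometry_factor
                 * ensemble.replicate_site_means(ph)[:, idx].sum(axis=1)
                 for ph in grid]
    pooled = [stoichiometry_factor * float(ensemble.pooled_site_means(ph)[idx].sum())
              for ph in grid]
    return _curve_from_replicate_stats(subject, grid, rep_stats, pooled,
                                       pooling, n_boot, seed)


def fit_hill(curve: TitrationCurve) -> HillFit:
    """Weighted nonlinear least-squares Hill fit of a per-site curve.

    Weights are inverse squared CI half-widths; if any half-width is
    degenerate (below 1e-9) the fit falls back to uniform weights.  The fit is
    flagged ``low_confidence`` when the curve never crosses 0.5 inside the pH
    grid or when the fitted pKa falls outside it — such midpoints are
    extrapolations and at best indicative.
    """
    ph = np.asarray(curve.pH, float)
    y = np.asarray(curve.mean, float)
    if ph.size < 3:
        raise ValueError("Hill fit needs at least 3 pH points")
    if y.min() < -1e-9 or y.max() > 1.0 + 1e-9:
        raise ValueError("Hill fit expects a per-site curve with values in [0, 1]")

    hw = curve.half_width
    sigma = None if np.any(hw < 1e-9) else hw
    p0 = (float(ph[np.argmin(np.abs(y - 0.5))]), 1.0)
    try:
        popt, pcov = curve_fit(
            hill_curve, ph, y, p0=p0, sigma=sigma,
            bounds=([-np.inf, 1e-6], [np.inf, np.inf]),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        perr = np.sqrt(np.diag(pcov))
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError as exc:
        return HillFit(pka=np.nan, hill_h=np.nan, pka_se=np.nan, hill_se=np.nan,
                       converged=False, low_confidence=True,
                       reason=f"fit did not converge: {exc}")
    low, reason = False, ""
    crosses = (y.min() - 0.5) * (y.max() - 0.5) <= 0
    if not crosses:
        low, reason = True, "curve never crosses 0.5 within the pH grid"
    elif not (ph.min() <= popt[0] <= ph.max()):
        low, reason = True, "fitted pKa lies outside the pH grid"
    return HillFit(pka=float(popt[0]), hill_h=float(popt[1]),
                   pka_se=float(perr[0]), hill_se=float(perr[1]),
                   converged=converged, low_confidence=low, reason=reason)
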