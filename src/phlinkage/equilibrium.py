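"""Monomer fraction under the 2M <-> D mass-action equilibrium.

Only *relative* dimerization free energies are available from the linkage
relation, and self-association makes absolute fractions depend on the total
chain concentration.  Both unknowns are folded into a single dimensionless
parameter

    kappa = K_dim * C_total      (K_dim the dimerization constant,
                                  C_total the total chain concentration),

and the equilibrium is parameterized by the monomer fraction f_ref at a
reference pH instead of by absolute concentrations.  Mass balance for the
fraction of chains in monomeric form reads

    f + 2 * kappa * f^2 = 1,

whose unique root in (0, 1] is f = 2 / (1 + sqrt(1 + 8 kappa)) (a form exact
in the kappa -> 0 limit).  A relative free-energy profile ddG(pH) then moves
kappa multiplicatively: kappa(pH) = kappa_ref * exp(-ddG(pH)/kT), and the
monomer fraction follows.  Fractions here always count chains, not particles:
f = 0.5 means half the chains are monomeric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import kT as thermal_kT
from .linkage import FreeEnergyProfile


def solve_mass_action(kappa):
    """Monomer fraction of chains at dimensionless kappa = K_dim * C_total.

    Returns the unique root in (0, 1] of 2*kappa*f^2 + f - 1 = 0, vectorized
    over ``kappa``.  kappa = 0 gives f = 1 exactly.
    """
    k = np.asarray(kappa, dtype=float)
    if np.any(k < 0) or not np.all(np.isfinite(k)):
        raise ValueError("kappa must be finite and >= 0")
    f = 2.0 / (1.0 + np.sqrt(1.0 + 8.0 * k))
    return float(f) if np.isscalar(kappa) else f


def kappa_from_fraction(f_ref):
    """Invert mass action: kappa giving monomer fraction f_ref in (0, 1)."""
    f = np.asarray(f_ref, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("reference monomer fractions must lie strictly in "
                         "(0, 1); endpoints make kappa degenerate or undefined")
    k = (1.0 - f) / (2.0 * f ** 2)
    return float(k) if np.isscalar(f_ref) else k


@dataclass
class MonomerFractionCurve:
    """Monomer fraction vs pH for a grid of reference fractions.

    ``table`` columns: f_ref, pH, f, shift (= f - f_ref), and ci_lo/ci_hi when
    uncertainty was propagated.  Fractions are fractions of chains.
    """

    ref_pH: float
    f_ref_grid: np.ndarray
    pH: np.ndarray
    table: pd.DataFrame
    temperature: float
    subject: str = ""

    def fraction(self, f_ref: float, pH: float) -> float:
        row = self.table[np.isclose(self.table["f_ref"], f_ref)
                         & np.isclose(self.table["pH"], pH)]
        if row.empty:
            raise KeyError(f"(f_ref={f_ref}, pH={pH}) not tabulated")
        return float(row["f"].iloc[0])


def _fractions_from_profile(values: np.ndarray, f_ref_grid: np.ndarray,
                            kT_val: float) -> np.ndarray:
    """(n_fref, n_pH) fractions from anchored ddG values (0 at reference)."""
    kappa_ref = kappa_from_fraction(f_ref_grid)
    kappa = kappa_ref[:, None] * np.exp(-values[None, :] / kT_val)
    return solve_mass_action(kappa)


def fraction_shift(
    profile: FreeEnergyProfile,
    ref_pH: float,
    f_ref_grid,
    temperature: float | None = None,
) -> MonomerFractionCurve:
    """pH-induced shift of the monomer fraction for each reference fraction.

    The profile is re-anchored at ``ref_pH`` if needed (an exact rigid shift).
    For every reference fraction f_ref the implied kappa_ref is scaled by
    exp(-ddG(pH)/kT) and the mass action re-solved.  Raising ddG (dimer
    destabilized) lowers kappa and raises the monomer fraction.
    """
    temperature = profile.temperature if temperature is None else temperature
    kT_val = thermal_kT(temperature)
    prof = profile if profile.ref_pH == ref_pH else profile.re_anchor(ref_pH)

    f_ref_grid = np.atleast_1d(np.asarray(f_ref_grid, dtype=float))
    kappa_from_fraction(f_ref_grid)       # validates the open-interval domain

    f = _fractions_from_profile(prof.values, f_ref_grid, kT_val)
    rows = []
    for i, fr in enumerate(f_ref_grid):
        for j, ph in enumerate(prof.pH):
            rows.append({"f_ref": fr, "pH": ph, "f": f[i, j],
                         "shift": f[i, j] - fr})
    return MonomerFractionCurve(
        ref_pH=float(ref_pH), f_ref_grid=f_ref_grid, pH=prof.pH,
        table=pd.DataFrame(rows), temperature=temperature,
        subject=prof.subject)


def fraction_uncertainty(
    profile: FreeEnergyProfile,
    ref_pH: float,
    f_ref_grid,
    temperature: float | None = None,
) -> MonomerFractionCurve:
    """Propagate ddG confidence bands to the monomer fraction.

    kappa (hence f) is strictly monotone in ddG, so the fraction band is the
    image of the ddG band endpoints: the upper ddG edge maps to the upper
    fraction edge.  Bands contain the point estimate by construction.
    """
    if profile.ci_lo is None or profile.ci_hi is None:
        raise ValueError("profile carries no confidence band to propagate")
    temperature = profile.temperature if temperature is None else temperature
    kT_val = thermal_kT(temperature)
    prof = profile if profile.ref_pH == ref_pH else profile.re_anchor(ref_pH)

    f_ref_grid = np.atleast_1d(np.asarray(f_ref_grid, dtype=float))
    kappa_from_fraction(f_ref_grid)

    f_mid = _fractions_from_profile(prof.values, f_ref_grid, kT_val)
    f_lo = _fractions_from_profile(prof.ci_lo, f_ref_grid, kT_val)
    f_hi = _fractions_from_profile(prof.ci_hi, f_ref_grid, kT_val)

    rows = []
    for i, fr in enumerate(f_ref_grid):
        for j, ph in enumerate(prof.pH):
            lo = min(f_lo[i, j], f_hi[i, j], f_mid[i, j])
            hi = max(f_lo[i, j], f_hi[i, j], f_mid[i, j])
            rows.append({"f_ref": fr, "pH": ph, "f": f_mid[i, j],
                         "shift": f_mid[i, j] - fr, "ci_lo": lo, "ci_hi": hi})
    return MonomerFractionCurve(
        ref_pH=float(ref_pH), f_ref_grid=f_ref_grid, pH=prof.pH,
        table=pd.DataFrame(rows), temperature=temperature,
        subject=prof.subject)
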