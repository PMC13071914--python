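"""Wyman linkage: from titration curves to pH-dependent dimerization energetics.

The pH derivative of the dimerization free energy 2M -> D equals the
difference in proton binding between product and reactants,

    d(dG)/d(pH) = ln(10) * kT * [Q_D(pH) - 2 Q_M(pH)],

where Q is the total protonation (proton binding) curve of each species.
Integrating from a reference pH yields the *relative* profile ddG(pH)
anchored at zero there — the linkage relation gives no absolute free energy.
Because Q is a sum of per-site curves, the profile decomposes exactly into
additive per-residue contributions

    dq_i(pH) = <x_i>_D,A + <x_i>_D,B - 2 <x_i>_M,

and restricting to a subset (e.g. the lumenal side, the physiologically
acidified compartment) is a partial sum of the same decomposition.

Integration uses the trapezoidal rule on the measured pH grid, with no
interpolation or extrapolation: the grid is the resolution.  A residue with a
flat contribution curve may still contribute strongly to the absolute dG; a
flat ddG_i only means it does not modulate the *pH sensitivity*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .constants import LN10, kT as thermal_kT
from .ensemble import ProtonationEnsemble
from .exact import _grid_index, exact_site_curves
from .model import SiteModel


@dataclass
class LinkageInput:
    """Site-matched monomer and dimer per-site protonation curves.

    ``monomer_curves`` is (n_pH, n_monomer_sites); ``dimer_curves`` is
    (n_pH, 2 * n_monomer_sites) with metadata rows mapping every monomer site
    label to exactly one site in each dimer chain.
    """

    pH: np.ndarray
    monomer_curves: np.ndarray
    dimer_curves: np.ndarray
    monomer_sites: pd.DataFrame
    dimer_sites: pd.DataFrame
    temperature: float

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        if not np.all(np.diff(self.pH) > 0):
            raise ValueError("pH grid must be strictly increasing")
        if self.monomer_curves.shape != (self.pH.size, len(self.monomer_sites)):
            raise ValueError("monomer curve matrix does not match grid/metadata")
        if self.dimer_curves.shape != (self.pH.size, len(self.dimer_sites)):
            raise ValueError("dimer curve matrix does not match grid/metadata")
        self._match = _match_sites(self.monomer_sites, self.dimer_sites)

    @property
    def labels(self) -> list[str]:
        return self.monomer_sites["label"].tolist()

    def subset_mask(self, subset: dict | None) -> np.ndarray:
        """Boolean mask over monomer sites from a filter dict."""
        mask = np.ones(len(self.monomer_sites), dtype=bool)
        if subset:
            if "compartment" in subset:
                mask &= (self.monomer_sites["compartment"]
                         == subset["compartment"]).to_numpy()
            if "labels" in subset:
                mask &= self.monomer_sites["label"].isin(subset["labels"]).to_numpy()
        return mask


def _match_sites(monomer_sites: pd.DataFrame, dimer_sites: pd.DataFrame):
    """For each monomer site, the (chain A, chain B) dimer column indices."""
    pairs = []
    unmatched = []
    for _, row in monomer_sites.iterrows():
        cols = {}
        for chain in ("A", "B"):
            hit = dimer_sites.index[(dimer_sites["label"] == row["label"])
                                    & (dimer_sites["chain"] == chain)].tolist()
            if len(hit) == 1:
                cols[chain] = hit[0]
        if set(cols) != {"A", "B"}:
            unmatched.append(row["label"])
        else:
            pairs.append((cols["A"], cols["B"]))
    if unmatched:
        raise ValueError("monomer sites without a unique match in both dimer "
                         f"chains: {unmatched}")
    return np.array(pairs, dtype=int)


@dataclass
class DeltaProtonation:
    """Per-residue and total proton-binding differences Q_D - 2 Q_M."""

    pH: np.ndarray
    per_residue: np.ndarray        # (n_pH, n_subset_residues), units: protons
    labels: list[str]
    subset: str

    @property
    def total(self) -> np.ndarray:
        return self.per_residue.sum(axis=1)


@dataclass
class FreeEnergyProfile:
    """Relative dimerization free energy vs pH, anchored at ``ref_pH``."""

    pH: np.ndarray
    values: np.ndarray             # kcal/mol, exactly 0 at ref_pH
    ref_pH: float
    subject: str
    temperature: float
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None

    def value_at(self, pH: float) -> float:
        return float(self.values[_grid_index(self.pH, pH)])

    def re_anchor(self, new_ref_pH: float) -> "FreeEnergyProfile":
        """Rigidly shift the profile to a new reference pH (exact operation)."""
        shift = self.value_at(new_ref_pH)
        return FreeEnergyProfile(
            pH=self.pH, values=self.values - shift, ref_pH=float(new_ref_pH),
            subject=self.subject, temperature=self.temperature,
            ci_lo=None if self.ci_lo is None else self.ci_lo - shift,
            ci_hi=None if self.ci_hi is None else self.ci_hi - shift)


def delta_protonation(inp: LinkageInput, subset: dict | None = None) -> DeltaProtonation:
    """dq_i(pH) = <x_i>_D,A + <x_i>_D,B - 2 <x_i>_M for the selected residues."""
    mask = inp.subset_mask(subset)
    if not mask.any():
        raise ValueError(f"subset {subset!r} selects no residues")
    a_cols = inp._match[mask, 0]
    b_cols = inp._match[mask, 1]
    dq = (inp.dimer_curves[:, a_cols] + inp.dimer_curves[:, b_cols]
          - 2.0 * inp.monomer_curves[:, mask])
    desc = "all" if not subset else ",".join(f"{k}={v}" for k, v in subset.items())
    return DeltaProtonation(pH=inp.pH, per_residue=dq,
                            labels=[l for l, m in zip(inp.labels, mask) if m],
                            subset=desc)


def integrate_linkage(
    delta_q: np.ndarray,
    pH_grid: np.ndarray,
    ref_pH: float,
    temperature: float,
    subject: str = "total",
) -> FreeEnergyProfile:
    """Trapezoid-integrate a proton-binding difference into a ddG profile.

    ddG(pH) = ln(10) * kT * integral from ref_pH to pH of dQ(u) du.  The
    reference pH must be a grid point (no silent interpolation); the profile
    is exactly zero there.
    """
    grid = np.asarray(pH_grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("pH grid must be strictly increasing")
    ref_idx = _grid_index(grid, ref_pH)
    dq = np.asarray(delta_q, dtype=float)
    cum = cumulative_trapezoid(dq, grid, initial=0.0)
    values = LN10 * thermal_kT(temperature) * (cum - cum[ref_idx])
    return FreeEnergyProfile(pH=grid, values=values, ref_pH=float(ref_pH),
                             subject=subject, temperature=temperature)


def residue_decomposition(
    inp: LinkageInput,
    ref_pH: float,
    subset: dict | None = None,
) -> tuple[FreeEnergyProfile, dict[str, FreeEnergyProfile]]:
    """Total ddG profile plus its exact per-residue additive decomposition."""
    dq = delta_protonation(inp, subset)
    total = integrate_linkage(dq.total, inp.pH, ref_pH, inp.temperature,
                              subject=f"total[{dq.subset}]")
    residues = {
        label: integrate_linkage(dq.per_residue[:, k], inp.pH, ref_pH,
                                 inp.temperature, subject=label)
        for k, label in enumerate(dq.labels)
    }
    return total, residues


def screen_key_residues(
    decomposition: dict[str, FreeEnergyProfile],
    threshold_kcal: float = 1.0,
) -> list[tuple[str, float]]:
    """Residues whose |contribution| reaches the threshold anywhere on the grid.

    Returns (label, max |ddG_i|) pairs ranked by magnitude, ties broken by
    label order.  The default 1 kcal/mol mirrors the screening level used to
    single out the dominant pH-sensing residues.
    """
    if threshold_kcal < 0:
        raise ValueError("threshold must be >= 0")
    scored = [(label, float(np.abs(p.values).max()))
              for label, p in decomposition.items()]
    hits = [(l, s) for l, s in scored if s >= threshold_kcal]
    return sorted(hits, key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# Construction of LinkageInput from ensembles or exact models
# ---------------------------------------------------------------------------

def linkage_input_from_ensembles(
    monomer: ProtonationEnsemble,
    dimer: ProtonationEnsemble,
    temperature: float,
) -> LinkageInput:
    """Point-estimate linkage input from sampled monomer and dimer ensembles."""
    grid_m, grid_d = monomer.pH_grid, dimer.pH_grid
    if grid_m.size != grid_d.size or not np.allclose(grid_m, grid_d):
        raise ValueError("monomer and dimer ensembles must share the pH grid")
    mon_curves = np.array([monomer.pooled_site_means(ph) for ph in grid_m])
    dim_curves = np.array([dimer.pooled_site_means(ph) for ph in grid_m])
    return LinkageInput(pH=grid_m, monomer_curves=mon_curves,
                        dimer_curves=dim_curves, monomer_sites=monomer.sites,
                        dimer_sites=dimer.sites, temperature=temperature)


def linkage_input_from_models(
    monomer: SiteModel,
    dimer: SiteModel,
    pH_grid: np.ndarray,
) -> LinkageInput:
    """Noise-free linkage input from exact enumeration of both models."""
    from .ensemble import site_metadata_frame
    grid = np.asarray(pH_grid, dtype=float)
    return LinkageInput(
        pH=grid,
        monomer_curves=exact_site_curves(monomer, grid),
        dimer_curves=exact_site_curves(dimer, grid),
        monomer_sites=site_metadata_frame(monomer.labels, monomer.chain,
                                          monomer.compartment),
        dimer_sites=site_metadata_frame(dimer.labels, dimer.chain,
                                        dimer.compartment),
        temperature=monomer.temperature,
    )


# ---------------------------------------------------------------------------
# Bootstrap error bands
# ---------------------------------------------------------------------------

@dataclass
class BootstrapProfileResult:
    total: FreeEnergyProfile
    residues: dict[str, FreeEnergyProfile] = field(default_factory=dict)
    n_boot: int = 0
    seed: int = 0
    degenerate: bool = False

    @property
    def total_se(self) -> np.ndarray:
        """Half the 68% band width: a bootstrap standard-error proxy per pH."""
        return (self.total.ci_hi - self.total.ci_lo) / 2.0


def bootstrap_profile(
    monomer: ProtonationEnsemble,
    dimer: ProtonationEnsemble,
    ref_pH: float,
    temperature: float,
    subset: dict | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    per_residue: bool = False,
) -> BootstrapProfileResult:
    """68% bootstrap bands on the ddG profile (and optionally per residue).

    Monomer and dimer replicates are resampled independently; the whole
    pipeline (site means -> dQ -> trapezoid integration) is recomputed per
    resample.  Bands are 16th-84th percentiles, widened if necessary to
    contain the point estimate.  A single replicate yields zero-width bands
    and sets ``degenerate``.
    """
    inp = linkage_input_from_ensembles(monomer, dimer, temperature)
    point_total, point_res = residue_decomposition(inp, ref_pH, subset)

    mon_tab = monomer.site_mean_table()    # (n_pH, R_m, n_sites)
    dim_tab = dimer.site_mean_table()
    r_m, r_d = mon_tab.shape[1], dim_tab.shape[1]
    degenerate = (r_m == 1 and r_d == 1)

    mask = inp.subset_mask(subset)
    labels = [l for l, m in zip(inp.labels, mask) if m]
    a_cols, b_cols = inp._match[mask, 0], inp._match[mask, 1]
    mon_cols = np.nonzero(mask)[0]

    rng = np.random.default_rng(seed)
    kT_val = thermal_kT(temperature)
    grid = inp.pH
    ref_idx = _grid_index(grid, ref_pH)

    idx_m = rng.integers(0, r_m, size=(n_boot, r_m))
    idx_d = rng.integers(0, r_d, size=(n_boot, r_d))
    totals = np.empty((n_boot, grid.size))
    res_vals = np.empty((n_boot, grid.size, len(labels))) if per_residue else None
    for b in range(n_boot):
        mon_means = mon_tab[:, idx_m[b], :].mean(axis=1)
        dim_means = dim_tab[:, idx_d[b], :].mean(axis=1)
        dq = (dim_means[:, a_cols] + dim_means[:, b_cols]
              - 2.0 * mon_means[:, mon_cols])
        cum = cumulative_trapezoid(dq, grid, axis=0, initial=0.0)
        prof = LN10 * kT_val * (cum - cum[ref_idx])
        totals[b] = prof.sum(axis=1)
        if per_residue:
            res_vals[b] = prof

    lo, hi = np.percentile(totals, (16.0, 84.0), axis=0)
    total = FreeEnergyProfile(
        pH=grid, values=point_total.values, ref_pH=float(ref_pH),
        subject=point_total.subject, temperature=temperature,
        ci_lo=np.minimum(lo, point_total.values),
        ci_hi=np.maximum(hi, point_total.values))

    residues: dict[str, FreeEnergyProfile] = {}
    if per_residue:
        r_lo, r_hi = np.percentile(res_vals, (16.0, 84.0), axis=0)
        for k, label in enumerate(labels):
            pt = point_res[label]
            residues[label] = FreeEnergyProfile(
                pH=grid, values=pt.values, ref_pH=float(ref_pH), subject=label,
                temperature=temperature,
                ci_lo=np.minimum(r_lo[:, k], pt.values),
                ci_hi=np.maximum(r_hi[:, k], pt.values))
    return BootstrapProfileResult(total=total, residues=residues, n_boot=n_boot,
                                  seed=seed, degenerate=degenerate)
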