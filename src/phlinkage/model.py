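"""Interacting titratable-site model.

A :class:`SiteModel` is an Ising-like description of ``n`` titratable sites.
Each site ``i`` has an intrinsic pKa (its midpoint in the absence of any
interaction) and sites interact through a symmetric matrix ``W`` of pairwise
energies between *protonated* states.  The semi-grand-canonical energy of a
binary microstate ``s`` (1 = proton bound) at a given pH is

    E(s; pH) = sum_i ln(10)*kT*(pH - pKa_int_i)*s_i
             + sum_{i<j} W_ij * s_i * s_j          [kcal/mol]

so that a single isolated site reproduces the Henderson-Hasselbalch curve
<x> = 1/(1 + 10^(pH - pKa)) exactly under Boltzmann statistics.

Sites carry metadata (residue label, chain tag, membrane compartment) used by
the downstream titration, correlation and linkage analyses.  Compartments are
"lumenal" or "stromal", the two membrane-flanking sides relevant for a
lumen-acidification pH sensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, LN10, kT

COMPARTMENTS = ("lumenal", "stromal")


@dataclass(frozen=True)
class SiteModel:
    """Definition of a system of interacting titratable sites.

    Parameters
    ----------
    pka_int
        Intrinsic pKa of each site (pH units).
    coupling
        Symmetric (n, n) matrix of pairwise protonated-protonated interaction
        energies in kcal/mol, zero diagonal.  Positive values penalize
        simultaneous protonation (anticooperative), negative values favor it.
    labels
        Residue identifiers, one per site (e.g. ``"Glu173"``).
    chain
        Chain tag per site (monomers conventionally use ``"M"``; dimers built
        with :func:`build_dimer_model` use ``"A"``/``"B"``).
    compartment
        ``"lumenal"`` or ``"stromal"`` per site.
    temperature
        Absolute temperature in kelvin; sets kT for sampling and enumeration.
    """

    pka_int: np.ndarray
    coupling: np.ndarray
    labels: tuple[str, ...]
    chain: tuple[str, ...]
    compartment: tuple[str, ...]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        pka = np.asarray(self.pka_int, dtype=float)
        w = np.asarray(self.coupling, dtype=float)
        object.__setattr__(self, "pka_int", pka)
        object.__setattr__(self, "coupling", w)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "chain", tuple(self.chain))
        object.__setattr__(self, "compartment", tuple(self.compartment))
        n = pka.shape[0]
        if pka.ndim != 1 or not np.all(np.isfinite(pka)):
            raise ValueError("pka_int must be a finite 1-D vector")
        if w.shape != (n, n):
            raise ValueError(f"coupling must be ({n}, {n}), got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("coupling energies must be finite")
        if not np.allclose(w, w.T, atol=0.0):
            raise ValueError("coupling matrix must be symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("coupling matrix must have an exactly zero diagonal")
        for name, vec in (("labels", self.labels), ("chain", self.chain),
                          ("compartment", self.compartment)):
            if len(vec) != n:
                raise ValueError(f"{name} must have length n_sites = {n}")
        bad = [c for c in self.compartment if c not in COMPARTMENTS]
        if bad:
            raise ValueError(f"unknown compartment tags {sorted(set(bad))}; "
                             f"expected one of {COMPARTMENTS}")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")

    @property
    def n_sites(self) -> int:
        return self.pka_int.shape[0]

    @property
    def kT(self) -> float:
        return kT(self.temperature)

    @property
    def site_ids(self) -> tuple[str, ...]:
        """Unique per-site identifiers ``label:chain``."""
        return tuple(f"{l}:{c}" for l, c in zip(self.labels, self.chain))

    def site_index(self, label: str, chain: str | None = None) -> int:
        """Index of a site by label (and chain if the label is ambiguous)."""
        hits = [i for i, l in enumerate(self.labels)
                if l == label and (chain is None or self.chain[i] == chain)]
        if not hits:
            raise KeyError(f"site {label!r}" + (f" chain {chain!r}" if chain else "")
                           + " not found")
        if len(hits) > 1:
            raise KeyError(f"site {label!r} is ambiguous (chains "
                           f"{[self.chain[i] for i in hits]}); pass chain=")
        return hits[0]

    def field_energies(self, pH: float) -> np.ndarray:
        """Per-site one-body energies ln(10)*kT*(pH - pKa_int) in kcal/mol."""
        return LN10 * self.kT * (pH - self.pka_int)

    def state_energy(self, states: np.ndarray, pH: float) -> np.ndarray:
        """Energy E(s; pH) in kcal/mol for one microstate or a stack of them."""
        s = np.atleast_2d(np.asarray(states, dtype=float))
        h = self.field_energies(pH)
        e = s @ h + 0.5 * np.einsum("ki,ij,kj->k", s, self.coupling, s)
        return e if np.asarray(states).ndim > 1 else float(e[0])


def build_dimer_model(
    monomer: SiteModel,
    interface_pka_shift: Sequence[float] | np.ndarray | None = None,
    interchain_coupling: Sequence[tuple[int, int, float]] = (),
) -> SiteModel:
    """Duplicate a monomer into a two-chain dimer model.

    The monomer's sites are copied into chains ``A`` and ``B``.  Each copy's
    intrinsic pKa is shifted by ``interface_pka_shift`` (per-site, pH units;
    negative shifts emulate interface interactions stabilizing the deprotonated
    acid).  Intra-chain couplings are copied into both chains; additional
    inter-chain couplings are given as ``(site_in_A, site_in_B, energy)``
    triples with monomer site indices.
    """
    n = monomer.n_sites
    if interface_pka_shift is None:
        shift = np.zeros(n)
    else:
        shift = np.asarray(interface_pka_shift, dtype=float)
    if shift.shape != (n,):
        raise ValueError(f"interface_pka_shift must have length {n}, got {shift.shape}")

    pka = np.concatenate([monomer.pka_int + shift, monomer.pka_int + shift])
    w = np.zeros((2 * n, 2 * n))
    w[:n, :n] = monomer.coupling
    w[n:, n:] = monomer.coupling
    for ia, ib, energy in interchain_coupling:
        ia, ib = int(ia), int(ib)
        if not (0 <= ia < n and 0 <= ib < n):
            raise IndexError(f"interchain pair ({ia}, {ib}) out of range for "
                             f"{n}-site monomer")
        w[ia, n + ib] += float(energy)
        w[n + ib, ia] += float(energy)
    return SiteModel(
        pka_int=pka,
        coupling=w,
        labels=monomer.labels + monomer.labels,
        chain=("A",) * n + ("B",) * n,
        compartment=monomer.compartment + monomer.compartment,
        temperature=monomer.temperature,
    )


def with_temperature(model: SiteModel, temperature: float) -> SiteModel:
    return replace(model, temperature=temperature)
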