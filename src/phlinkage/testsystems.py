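"""Synthetic titratable systems used across tests, analyses and acceptance runs.

The centerpiece is a "toy pH-sensor" fixture loosely patterned on a
lumen-acidification-sensing membrane protein: a 16-site monomer (10 lumenal +
6 stromal acids) dimerized into a 32-site two-chain model.  The fixture
plants a known ground truth that every downstream analysis must recover:

* three lumenal residues (Glu55, Glu69, Glu173) get negative interface pKa
  shifts in the dimer — interface interactions stabilizing their charged
  forms — and are therefore the only lumenal residues contributing more than
  1 kcal/mol to the pH dependence of the dimerization free energy;
* two stromal inter-chain couplings (Glu141:A-Glu141:B at +2.5 kcal/mol,
  Glu37:A-Glu105:B at -2.5 kcal/mol) create dimer-only correlation edges of
  opposite signs;
* one intra-chain lumen-stroma coupling (Glu159-Glu20 at -3.0 kcal/mol),
  present identically in monomer and dimer, produces a positive
  cross-compartment correlation edge while cancelling exactly in the linkage
  free energy;
* a few sites exchange protons slowly (small flip-attempt probabilities),
  giving long protonation correlation times and noisy titration curves.

Lumenal glutamate pKa values sit above the aqueous reference of 4.25, in the
5-6.5 window typical of buried/interface acids in pH-sensing proteins.  All
coupling magnitudes were fixed from the exact enumeration oracle at design
time so that planted pairs correlate strongly (|phi| ~ 0.8 at the most
sensitive pH) and planted-shift residues clear the 1 kcal/mol screen.
"""

from __future__ import annotations

import numpy as np

from .model import SiteModel, build_dimer_model

#: Aqueous reference pKa of glutamate.
GLU_WATER_PKA = 4.25

# label, compartment, intrinsic pKa, flip-attempt probability
_TOY_SITES = [
    ("Glu55",  "lumenal", 5.2, 0.02),   # slow exchanger, trapped protonation
    ("Glu69",  "lumenal", 5.0, 1.0),
    ("Glu76",  "lumenal", 5.9, 1.0),
    ("Glu78",  "lumenal", 6.2, 0.10),   # moderately slow
    ("Glu94",  "lumenal", 4.6, 1.0),
    ("Glu159", "lumenal", 5.8, 1.0),
    ("Glu173", "lumenal", 6.3, 1.0),
    ("Glu180", "lumenal", 6.5, 1.0),
    ("Glu182", "lumenal", 5.5, 1.0),
    ("Asp157", "lumenal", 3.9, 1.0),
    ("Glu20",  "stromal", 5.0, 1.0),
    ("Asp21",  "stromal", 4.0, 1.0),
    ("Glu37",  "stromal", 4.8, 1.0),
    ("Asp98",  "stromal", 4.2, 1.0),
    ("Glu105", "stromal", 5.2, 1.0),
    ("Glu141", "stromal", 5.5, 0.05),   # slow exchanger
]

#: Intra-chain couplings (label_i, label_j, kcal/mol); the single planted
#: lumen-stroma pair.  Negative: simultaneous protonation favored.
TOY_INTRACHAIN = [("Glu159", "Glu20", -3.0)]

#: Dimer interface pKa shifts (pH units) — the planted "key residues".
TOY_INTERFACE_SHIFTS = {"Glu55": -1.3, "Glu69": -1.1, "Glu173": -1.5}

#: Inter-chain couplings (label_in_A, label_in_B, kcal/mol), dimer only.
TOY_INTERCHAIN = [("Glu141", "Glu141", +2.5), ("Glu37", "Glu105", -2.5)]

#: Default study conditions for the fixture.
TOY_PH_GRID = np.round(np.arange(3.0, 8.0 + 1e-9, 0.25), 10)
TOY_N_REPLICATES = 5
TOY_N_FRAMES = 100_000
TOY_SEED = 42


def toy_monomer() -> SiteModel:
    """16-site monomer of the toy pH-sensor fixture (chain tag ``M``)."""
    labels = tuple(s[0] for s in _TOY_SITES)
    comp = tuple(s[1] for s in _TOY_SITES)
    pka = np.array([s[2] for s in _TOY_SITES])
    n = len(labels)
    w = np.zeros((n, n))
    index = {l: i for i, l in enumerate(labels)}
    for a, b, energy in TOY_INTRACHAIN:
        i, j = index[a], index[b]
        w[i, j] = w[j, i] = energy
    return SiteModel(pka_int=pka, coupling=w, labels=labels,
                     chain=("M",) * n, compartment=comp)


def toy_dimer(monomer: SiteModel | None = None) -> SiteModel:
    """32-site dimer: planted interface shifts plus two inter-chain couplings."""
    monomer = monomer or toy_monomer()
    index = {l: i for i, l in enumerate(monomer.labels)}
    shift = np.array([TOY_INTERFACE_SHIFTS.get(l, 0.0) for l in monomer.labels])
    pairs = [(index[a], index[b], energy) for a, b, energy in TOY_INTERCHAIN]
    return build_dimer_model(monomer, interface_pka_shift=shift,
                             interchain_coupling=pairs)


def toy_flip_probs(model: SiteModel) -> np.ndarray:
    """Per-site flip-attempt probabilities for either toy system."""
    table = {s[0]: s[3] for s in _TOY_SITES}
    return np.array([table[l] for l in model.labels])


def planted_key_residues() -> list[str]:
    """Residues whose interface shifts drive the pH-dependent energetics."""
    return sorted(TOY_INTERFACE_SHIFTS)


def planted_coupling_pairs(dimer: SiteModel | None = None):
    """Planted coupled site pairs as (site_id_i, site_id_j, energy) triples.

    Covers the two inter-chain pairs and the lumen-stroma pair in both dimer
    chains, using ``label:chain`` site ids.
    """
    pairs = [(f"{a}:A", f"{b}:B", w) for a, b, w in TOY_INTERCHAIN]
    for a, b, w in TOY_INTRACHAIN:
        pairs.append((f"{a}:A", f"{b}:A", w))
        pairs.append((f"{a}:B", f"{b}:B", w))
    return pairs


def uncoupled_single_site(pka: float = GLU_WATER_PKA) -> SiteModel:
    """One isolated glutamate-like site: the Henderson-Hasselbalch reference."""
    return SiteModel(pka_int=[pka], coupling=[[0.0]], labels=("Glu",),
                     chain=("M",), compartment=("lumenal",))


def coupled_pair(pka1: float, pka2: float, energy: float,
                 compartments=("lumenal", "lumenal")) -> SiteModel:
    """Two interacting sites — the minimal cooperative/anticooperative system."""
    return SiteModel(pka_int=[pka1, pka2],
                     coupling=[[0.0, energy], [energy, 0.0]],
                     labels=("s1", "s2"), chain=("M", "M"),
                     compartment=tuple(compartments))


def calibration_monomer() -> SiteModel:
    """Small 4-site system used for bootstrap-coverage calibration runs."""
    return SiteModel(
        pka_int=[4.2, 5.0, 5.8, 6.4],
        coupling=[[0.0, 0.0, -1.5, 0.0],
                  [0.0, 0.0, 0.0, 0.0],
                  [-1.5, 0.0, 0.0, 0.0],
                  [0.0, 0.0, 0.0, 0.0]],
        labels=("c1", "c2", "c3", "c4"),
        chain=("M",) * 4,
        compartment=("lumenal", "lumenal", "stromal", "stromal"),
    )


def calibration_dimer(monomer: SiteModel | None = None) -> SiteModel:
    monomer = monomer or calibration_monomer()
    return build_dimer_model(monomer,
                             interface_pka_shift=[0.0, -0.8, 0.0, 0.0],
                             interchain_coupling=[(3, 3, 2.0)])
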