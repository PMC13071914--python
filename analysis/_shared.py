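"""Shared helpers for the numbered analysis drivers.

The drivers all work on the same toy pH-sensor fixture run (reduced study:
5 replicates x 20k sweeps on the 0.25 pH grid).  Sampled states are cached as
a compressed archive under scratch/ so later drivers reuse the exact same
ensembles; the cache key includes the study conditions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from phlinkage.ensemble import ProtonationEnsemble, ProtonationTrajectory
from phlinkage.sampling import sample_ensemble
from phlinkage.testsystems import (TOY_PH_GRID, toy_dimer, toy_flip_probs,
                                   toy_monomer)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"

N_FRAMES = 20_000
N_REPLICATES = 5
SEED = 42


def get_toy_ensembles() -> tuple[ProtonationEnsemble, ProtonationEnsemble]:
    """Sampled toy monomer and dimer ensembles, cached across drivers."""
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cache = SCRATCH / f"toy_f{N_FRAMES}_r{N_REPLICATES}_s{SEED}.npz"
    monomer, dimer = toy_monomer(), toy_dimer()
    if cache.exists():
        return tuple(_load(cache, system, model)
                     for system, model in (("monomer", monomer),
                                           ("dimer", dimer)))
    mon = sample_ensemble(monomer, TOY_PH_GRID, N_REPLICATES, N_FRAMES,
                          seed=SEED, flip_attempt_prob=toy_flip_probs(monomer),
                          system="monomer")
    dim = sample_ensemble(dimer, TOY_PH_GRID, N_REPLICATES, N_FRAMES,
                          seed=SEED + 1, flip_attempt_prob=toy_flip_probs(dimer),
                          system="dimer")
    arrays = {}
    for system, ens in (("monomer", mon), ("dimer", dim)):
        for ph in ens.pH_grid:
            for t in ens.at(ph):
                arrays[f"{system}|{ph}|{t.replicate}"] = t.states
    np.savez_compressed(cache, **arrays)
    return mon, dim


def _load(cache, system, model):
    from phlinkage.ensemble import site_metadata_frame
    ens = ProtonationEnsemble(
        system=system,
        sites=site_metadata_frame(model.labels, model.chain,
                                  model.compartment))
    with np.load(cache) as data:
        for key in data.files:
            sys_tag, ph, rep = key.split("|")
            if sys_tag == system:
                ens.add(ProtonationTrajectory(system=system, pH=float(ph),
                                              replicate=int(rep),
                                              states=data[key]))
    return ens
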