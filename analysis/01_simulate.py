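#!/usr/bin/env python
"""Sample the toy pH-sensor fixture and check it against the exact oracle.

Generates the monomer (16 titratable sites: 10 lumenal, 6 stromal) and dimer
(32 sites, with planted interface pKa shifts on Glu55/Glu69/Glu173 and two
stromal inter-chain couplings) at 21 pH values from 3 to 8, 5 replicates of
20,000 Monte Carlo sweeps each.  Verifies that every sampled per-site mean
agrees with exact enumeration and writes a small demonstration slice of the
occupancy format plus a run summary.
"""

import json

import numpy as np

from _shared import RESULTS, SCRATCH, SEED, N_FRAMES, N_REPLICATES, \
    get_toy_ensembles
from phlinkage.exact import enumerate_equilibrium
from phlinkage.io import write_occupancy
from phlinkage.testsystems import TOY_PH_GRID, toy_dimer, toy_monomer


def main():
    RESULTS.mkdir(exist_ok=True)
    mon, dim = get_toy_ensembles()
    models = {"monomer": toy_monomer(), "dimer": toy_dimer()}

    worst = 0.0
    for system, ens in (("monomer", mon), ("dimer", dim)):
        model = models[system]
        for ph in (3.5, 5.0, 6.5):
            exact = enumerate_equilibrium(model, ph).mean
            reps = ens.replicate_site_means(ph)
            # SE estimated from 5 replicates is noisy; floor it at the
            # independent-binomial scale so lucky low-scatter replicates do
            # not inflate z
            n_obs = reps.shape[0] * ens.at(ph)[0].n_frames
            se = np.maximum(reps.std(axis=0, ddof=1) / np.sqrt(reps.shape[0]),
                            np.sqrt(np.maximum(exact * (1 - exact), 1e-4)
                                    / n_obs))
            worst = max(worst, float(np.max(np.abs(reps.mean(0) - exact) / se)))
    print(f"sampled vs enumerated per-site means: worst |z| = {worst:.2f} "
          "(should stay within a few sigma)")

    # demonstration slice of the occupancy format: first 50 frames at pH 5
    demo = {}
    for system, ens in (("monomer", mon), ("dimer", dim)):
        sliced = type(ens)(system=system, sites=ens.sites)
        for t in ens.at(5.0)[:2]:
            sliced.add(type(t)(system=system, pH=5.0, replicate=t.replicate,
                               states=t.states[:50]))
        demo[system] = sliced
    write_occupancy(demo, RESULTS / "occupancy_demo.tsv",
                    RESULTS / "sites.tsv")

    meta = {"pH_grid": [float(p) for p in TOY_PH_GRID],
            "n_replicates": N_REPLICATES, "n_frames": N_FRAMES, "seed": SEED,
            "worst_mean_z": worst,
            "cache": str(SCRATCH)}
    (RESULTS / "toy_run_meta.json").write_text(json.dumps(meta, indent=2))
    print(f"ensembles cached under {SCRATCH}")
    print(f"occupancy format demo -> {RESULTS/'occupancy_demo.tsv'}")


if __name__ == "__main__":
    main()
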