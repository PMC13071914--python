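"""Semi-grand-canonical Monte Carlo sampling of protonation states.

The sampler performs single-site Metropolis flips: one "frame" is one full
sweep over the sites in fixed order.  At each visit, site ``i`` attempts a
flip with probability ``flip_attempt_prob[i]`` (the knob emulating kinetically
slow proton exchangers) and accepts it with probability
``min(1, exp(-dE/kT))``, which satisfies detailed balance with respect to the
microstate Boltzmann distribution of the model.  Chains are initialized from
the intrinsic (coupling-free) Henderson-Hasselbalch occupancies, so a short
burn-in suffices for the weak-to-moderate couplings this package targets.

All randomness derives from a single integer seed through
``numpy.random.SeedSequence``; identical (model, settings, seed) gives
bit-identical trajectories.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .ensemble import ProtonationEnsemble, ProtonationTrajectory, site_metadata_frame
from .model import SiteModel

DEFAULT_BURN_IN = 500


@njit(cache=True)
def _run_chain(h, kT, nbr_idx, nbr_w, nbr_ptr, flip_prob, n_frames, n_burn,
               seed, out):  # pragma: no cover - exercised through sample_ensemble
    n_sites = h.shape[0]
    np.random.seed(seed)
    s = np.empty(n_sites, np.int8)
    for i in range(n_sites):
        p1 = 1.0 / (1.0 + np.exp(h[i] / kT))
        s[i] = 1 if np.random.random() < p1 else 0
    for t in range(n_burn + n_frames):
        for i in range(n_sites):
            if flip_prob[i] < 1.0 and np.random.random() >= flip_prob[i]:
                continue
            field = h[i]
            for k in range(nbr_ptr[i], nbr_ptr[i + 1]):
                if s[nbr_idx[k]] == 1:
                    field += nbr_w[k]
            dE = field if s[i] == 0 else -field
            if dE <= 0.0 or np.random.random() < np.exp(-dE / kT):
                s[i] = 1 - s[i]
        if t >= n_burn:
            out[t - n_burn, :] = s


def _neighbor_lists(coupling: np.ndarray):
    """CSR-style neighbor lists of the coupling graph."""
    n = coupling.shape[0]
    idx, w, ptr = [], [], [0]
    for i in range(n):
        nz = np.nonzero(coupling[i])[0]
        idx.extend(int(j) for j in nz)
        w.extend(float(coupling[i, j]) for j in nz)
        ptr.append(len(idx))
    return (np.array(idx, dtype=np.int64), np.array(w, dtype=np.float64),
            np.array(ptr, dtype=np.int64))


def sample_ensemble(
    model: SiteModel,
    pH_grid,
    n_replicates: int,
    n_frames: int,
    seed: int,
    flip_attempt_prob=None,
    n_burn: int = DEFAULT_BURN_IN,
    system: str = "monomer",
) -> ProtonationEnsemble:
    """Sample a protonation ensemble on a pH grid.

    Parameters
    ----------
    flip_attempt_prob
        Per-site probability in (0, 1] that a site attempts a flip during a
        sweep; 1 everywhere by default.  Values << 1 produce slow exchangers
        with long protonation correlation times.
    n_burn
        Equilibration sweeps discarded before recording.

    Returns
    -------
    ProtonationEnsemble
        ``n_replicates`` independent trajectories of ``n_frames`` sweeps at
        every grid pH, with the model's site metadata attached.
    """
    grid = np.atleast_1d(np.asarray(pH_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("pH grid is empty")
    if not np.all(np.isfinite(grid)):
        raise ValueError("pH grid contains non-finite values")
    if n_frames < 1 or n_replicates < 1:
        raise ValueError("n_frames and n_replicates must be >= 1")
    n = model.n_sites
    if flip_attempt_prob is None:
        fp = np.ones(n)
    else:
        fp = np.asarray(flip_attempt_prob, dtype=float)
        if fp.shape != (n,):
            raise ValueError(f"flip_attempt_prob must have length {n}")
        if np.any(fp <= 0) or np.any(fp > 1):
            raise ValueError("flip_attempt_prob entries must lie in (0, 1]")

    nbr_idx, nbr_w, nbr_ptr = _neighbor_lists(model.coupling)
    n_chains = grid.size * n_replicates
    seeds = np.random.SeedSequence(seed).generate_state(n_chains) % (2 ** 31)

    ensemble = ProtonationEnsemble(
        system=system,
        sites=site_metadata_frame(model.labels, model.chain, model.compartment),
    )
    chain = 0
    for ph in grid:
        h = model.field_energies(ph)
        for rep in range(n_replicates):
            out = np.empty((n_frames, n), dtype=np.int8)
            _run_chain(h, model.kT, nbr_idx, nbr_w, nbr_ptr, fp,
                       n_frames, n_burn, int(seeds[chain]), out)
            ensemble.add(ProtonationTrajectory(
                system=system, pH=float(ph), replicate=rep, states=out))
            chain += 1
    return ensemble
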