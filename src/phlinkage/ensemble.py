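"""Containers for per-pH protonation-state ensembles.

A :class:`ProtonationTrajectory` is one replicate's binary (frames x sites)
protonation record at a single pH; a :class:`ProtonationEnsemble` collects all
replicates on a pH grid for one system (monomer or dimer) together with the
site metadata needed by the analyses (labels, chain tags, compartments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYSTEMS = ("monomer", "dimer")


@dataclass
class ProtonationTrajectory:
    """Binary protonation time series of one replicate at one pH."""

    system: str
    pH: float
    replicate: int
    states: np.ndarray              # (n_frames, n_sites), values in {0, 1}
    frame_spacing: float | str = "steps"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 2 or self.states.shape[0] < 1:
            raise ValueError("states must be a (frames >= 1, n_sites) matrix")
        vals = np.unique(self.states)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"states must be binary; found values {vals[:5]}")
        if self.system not in SYSTEMS:
            raise ValueError(f"system must be one of {SYSTEMS}, got {self.system!r}")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    def site_means(self) -> np.ndarray:
        return self.states.mean(axis=0)


def _ph_key(pH: float) -> float:
    # canonical float key to make dict lookups robust to tiny formatting noise
    return round(float(pH), 9)


@dataclass
class ProtonationEnsemble:
    """All replicates of one system on a pH grid, plus site metadata.

    ``sites`` is a DataFrame with columns ``site_id``, ``label``, ``chain``,
    ``compartment`` in the column order of every trajectory's state matrix.
    """

    system: str
    sites: pd.DataFrame
    trajectories: dict[float, list[ProtonationTrajectory]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"site_id", "label", "chain", "compartment"}
        missing = required - set(self.sites.columns)
        if missing:
            raise ValueError(f"site metadata lacks columns {sorted(missing)}")
        self.sites = self.sites.reset_index(drop=True)
        self.trajectories = {_ph_key(ph): list(trs)
                             for ph, trs in self.trajectories.items()}
        for ph, trs in self.trajectories.items():
            reps = [t.replicate for t in trs]
            if len(set(reps)) != len(reps):
                raise ValueError(f"duplicate replicate ids at pH {ph}: {reps}")
            for t in trs:
                if t.n_sites != self.n_sites:
                    raise ValueError(
                        f"trajectory at pH {ph} has {t.n_sites} sites, "
                        f"metadata has {self.n_sites}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def pH_grid(self) -> np.ndarray:
        return np.array(sorted(self.trajectories), dtype=float)

    def add(self, trajectory: ProtonationTrajectory) -> None:
        self.trajectories.setdefault(_ph_key(trajectory.pH), []).append(trajectory)

    def at(self, pH: float) -> list[ProtonationTrajectory]:
        key = _ph_key(pH)
        if key not in self.trajectories:
            raise KeyError(f"pH {pH} not present; grid is {list(self.pH_grid)}")
        return self.trajectories[key]

    def n_replicates(self, pH: float) -> int:
        return len(self.at(pH))

    def site_index(self, label: str, chain: str | None = None) -> int:
        mask = self.sites["label"] == label
        if chain is not None:
            mask &= self.sites["chain"] == chain
        hits = self.sites.index[mask].tolist()
        if not hits:
            raise KeyError(f"site {label!r}" + (f" chain {chain!r}" if chain else "")
                           + " not in ensemble")
        if len(hits) > 1:
            raise KeyError(f"site {label!r} is ambiguous across chains; pass chain=")
        return hits[0]

    def subset_indices(self, compartment: str | None = None,
                       labels: list[str] | None = None,
                       chain: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_sites, dtype=bool)
        if compartment is not None:
            mask &= (self.sites["compartment"] == compartment).to_numpy()
        if labels is not None:
            mask &= self.sites["label"].isin(labels).to_numpy()
        if chain is not None:
            mask &= (self.sites["chain"] == chain).to_numpy()
        return np.nonzero(mask)[0]

    # -- statistics used downstream ---------------------------------------

    def replicate_site_means(self, pH: float) -> np.ndarray:
        """(n_replicates, n_sites) per-replicate time-average protonation."""
        return np.array([t.site_means() for t in self.at(pH)])

    def pooled_site_means(self, pH: float) -> np.ndarray:
        """Frame-pooled per-site means (frames weighted equally across replicates)."""
        trs = self.at(pH)
        total = sum(t.states.sum(axis=0) for t in trs)
        frames = sum(t.n_frames for t in trs)
        return total / frames

    def pooled_states(self, pH: float) -> np.ndarray:
        """All frames of all replicates stacked, (sum_frames, n_sites)."""
        return np.concatenate([t.states for t in self.at(pH)], axis=0)

    def site_mean_table(self) -> np.ndarray:
        """(n_pH, n_replicates, n_sites) replicate means over the sorted grid.

        Requires the replicate count to be constant across pH.
        """
        grids = [self.replicate_site_means(ph) for ph in self.pH_grid]
        n_reps = {g.shape[0] for g in grids}
        if len(n_reps) != 1:
            raise ValueError(f"replicate count varies across pH: {sorted(n_reps)}")
        return np.stack(grids)


def site_metadata_frame(labels, chains, compartments) -> pd.DataFrame:
    """Build the canonical site-metadata table (site_id = ``label:chain``)."""
    return pd.DataFrame({
        "site_id": [f"{l}:{c}" for l, c in zip(labels, chains)],
        "label": list(labels),
        "chain": list(chains),
        "compartment": list(compartments),
    })
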