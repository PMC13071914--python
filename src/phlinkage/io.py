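"""File formats: occupancy tables, site metadata, run configuration.

The canonical on-disk representation of a protonation ensemble is a
long-format TSV with key columns ``system, pH, replicate, frame`` followed by
one 0/1 column per site (header row = site ids ``label:chain``), plus a
companion site-metadata TSV (``site_id, label, chain, compartment,
monomer_site_match``).  pH lives in a data column rather than only in file
names so arbitrary grids round-trip losslessly; a whitespace "matrix" dialect
with pH/replicate encoded as filename tokens (``...pH5.0_rep2...``) is also
read, since that layout is common for constant-pH MD occupancy dumps.

Validation is strict and locates problems by line number: non-binary states,
duplicate (system, pH, replicate, frame) keys and unresolvable dimer-monomer
site matches are all fatal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import ProtonationEnsemble, ProtonationTrajectory
from .model import SiteModel

KEY_COLUMNS = ["system", "pH", "replicate", "frame"]
METADATA_COLUMNS = ["site_id", "label", "chain", "compartment",
                    "monomer_site_match"]


class OccupancyFormatError(ValueError):
    """Malformed occupancy or metadata input, with file location."""


# ---------------------------------------------------------------------------
# Occupancy tables
# ---------------------------------------------------------------------------

def write_occupancy(
    ensembles: dict[str, ProtonationEnsemble],
    occupancy_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write ensembles ({"monomer": ..., "dimer": ...}) as TSV + metadata TSV."""
    meta_frames = []
    blocks = []
    for system, ens in ensembles.items():
        meta = ens.sites.copy()
        meta["monomer_site_match"] = [
            f"{l}:M" if system == "dimer" else "" for l in meta["label"]]
        meta.insert(0, "system", system)
        meta_frames.append(meta)
        for ph in ens.pH_grid:
            for tr in ens.at(ph):
                block = pd.DataFrame(tr.states,
                                     columns=ens.sites["site_id"].tolist())
                block.insert(0, "frame", np.arange(tr.n_frames))
                block.insert(0, "replicate", tr.replicate)
                block.insert(0, "pH", tr.pH)
                block.insert(0, "system", system)
                blocks.append(block)
    table = pd.concat(blocks, ignore_index=True)
    # sites differ between systems; absent columns stay empty
    table.to_csv(occupancy_path, sep="\t", index=False, float_format="%.10g")
    pd.concat(meta_frames, ignore_index=True).to_csv(
        metadata_path, sep="\t", index=False)


def read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str,
                       keep_default_na=False)
    missing = {"system", *METADATA_COLUMNS} - set(meta.columns)
    if missing:
        raise OccupancyFormatError(
            f"{metadata_path}: metadata lacks columns {sorted(missing)}")
    # every dimer site must resolve to a monomer site id
    monomer_ids = set(meta.loc[meta["system"] == "monomer", "site_id"])
    dimer = meta[meta["system"] == "dimer"]
    bad = dimer.loc[~dimer["monomer_site_match"].isin(monomer_ids)]
    if len(dimer) and len(bad):
        lines = [int(i) + 2 for i in bad.index[:5]]  # +2: header + 0-base
        raise OccupancyFormatError(
            f"{metadata_path}: dimer sites with unresolvable monomer_site_match "
            f"{bad['site_id'].tolist()[:5]} (lines {lines})")
    return meta


def read_occupancy(
    occupancy_path: str | Path,
    metadata_path: str | Path,
) -> dict[str, ProtonationEnsemble]:
    """Read a long-format occupancy TSV into per-system ensembles."""
    meta = read_metadata(metadata_path)
    table = pd.read_csv(occupancy_path, sep="\t")
    missing = set(KEY_COLUMNS) - set(table.columns)
    if missing:
        raise OccupancyFormatError(
            f"{occupancy_path}: missing key columns {sorted(missing)}")

    dup = table.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        line = int(table.index[dup][0]) + 2
        raise OccupancyFormatError(
            f"{occupancy_path}: duplicate (system, pH, replicate, frame) key "
            f"at line {line}")

    ensembles: dict[str, ProtonationEnsemble] = {}
    for system, sys_table in table.groupby("system", sort=True):
        sys_meta = (meta[meta["system"] == system]
                    .drop(columns=["system"]).reset_index(drop=True))
        site_cols = sys_meta["site_id"].tolist()
        absent = set(site_cols) - set(sys_table.columns)
        if absent:
            raise OccupancyFormatError(
                f"{occupancy_path}: system {system!r} lacks site columns "
                f"{sorted(absent)}")
        states_block = sys_table[site_cols]
        values = states_block.to_numpy()
        bad = ~np.isin(values, (0, 1)) | pd.isna(values)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            line = int(states_block.index[r]) + 2
            raise OccupancyFormatError(
                f"{occupancy_path}: non-binary state value "
                f"{values[r, c]!r} in column {site_cols[c]!r} at line {line}")
        sys_meta = sys_meta.drop(columns=["monomer_site_match"])
        ens = ProtonationEnsemble(system=str(system), sites=sys_meta)
        for (ph, rep), group in sys_table.groupby(["pH", "replicate"]):
            frames = group.sort_values("frame")
            ens.add(ProtonationTrajectory(
                system=str(system), pH=float(ph), replicate=int(rep),
                states=frames[site_cols].to_numpy(dtype=np.int8)))
        ensembles[str(system)] = ens
    return ensembles


_PH_TOKEN = re.compile(r"pH(\d+(?:\.\d+)?)")
_REP_TOKEN = re.compile(r"rep(\d+)")


def read_occupancy_matrix(
    path: str | Path,
    system: str,
    site_ids: list[str] | None = None,
) -> ProtonationTrajectory:
    """Read a whitespace occupancy matrix with pH/replicate filename tokens.

    The file holds a frames x sites 0/1 matrix (an optional first header line
    of site ids is detected and used when ``site_ids`` is None).  The pH is
    taken from a ``pH<value>`` token in the file name and the replicate from
    an optional ``rep<n>`` token (default 0), e.g. ``monomer_pH5.0_rep2.dat``.
    """
    path = Path(path)
    m = _PH_TOKEN.search(path.name)
    if not m:
        raise OccupancyFormatError(
            f"{path.name}: no 'pH<value>' token in filename (e.g. 'pH5.0')")
    ph = float(m.group(1))
    rep_m = _REP_TOKEN.search(path.name)
    replicate = int(rep_m.group(1)) if rep_m else 0

    with open(path) as fh:
        first = fh.readline().split()
    has_header = any(not tok.lstrip("+-").replace(".", "", 1).isdigit()
                     for tok in first)
    table = pd.read_csv(path, sep=r"\s+",
                        header=0 if has_header else None)
    values = table.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise OccupancyFormatError(
            f"{path}: non-binary value {values[r, c]!r} at line "
            f"{int(r) + (2 if has_header else 1)}")
    return ProtonationTrajectory(system=system, pH=ph, replicate=replicate,
                                 states=values.astype(np.int8))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parsed pipeline configuration (see ``example_config`` for the layout)."""

    model: SiteModel                       # monomer
    dimer: SiteModel
    flip_probs: np.ndarray                 # per monomer site; dimer tiles it
    pH_grid: np.ndarray
    n_replicates: int = 5
    n_frames: int = 10_000
    seed: int = 42
    burn_in: int = 500
    temperature: float = 298.15
    ref_pH_linkage: float = 3.0
    ref_pH_fraction: float = 7.5
    correlation_threshold: float = 0.3
    n_boot: int = 1000
    subset: dict | None = None
    f_ref_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.1, 0.95, 0.1))
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.pH_grid, dtype=float)
        for name, ref in (("linkage", self.ref_pH_linkage),
                          ("fraction", self.ref_pH_fraction)):
            if not np.isclose(grid, ref, atol=1e-9).any():
                raise ValueError(
                    f"ref_pH_{name} = {ref} is not a point of the pH grid")


def _parse_grid(spec) -> np.ndarray:
    if isinstance(spec, dict):
        return np.round(np.arange(spec["start"], spec["stop"] + 1e-9,
                                  spec["step"]), 10)
    return np.asarray(spec, dtype=float)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration into models plus analysis settings."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    sites = cfg["sites"]
    labels = tuple(s["label"] for s in sites)
    index = {l: i for i, l in enumerate(labels)}
    n = len(sites)
    w = np.zeros((n, n))
    for c in cfg.get("couplings", []):
        i, j = index[str(c["i"])], index[str(c["j"])]
        if i == j:
            raise ValueError(f"self-coupling on {c['i']!r}")
        w[i, j] = w[j, i] = float(c["energy"])
    analysis = cfg.get("analysis", {})
    temperature = float(analysis.get("temperature", 298.15))
    monomer = SiteModel(
        pka_int=np.array([float(s["pka_int"]) for s in sites]),
        coupling=w,
        labels=labels,
        chain=tuple(s.get("chain", "M") for s in sites),
        compartment=tuple(s["compartment"] for s in sites),
        temperature=temperature,
    )
    flip = np.array([float(s.get("flip_prob", 1.0)) for s in sites])

    dimer_cfg = cfg.get("dimer", {})
    shift_map = dimer_cfg.get("interface_pka_shift", {}) or {}
    shift = np.array([float(shift_map.get(l, 0.0)) for l in labels])
    pairs = [(index[str(c["i"])], index[str(c["j"])], float(c["energy"]))
             for c in dimer_cfg.get("interchain_couplings", [])]
    from .model import build_dimer_model
    dimer = build_dimer_model(monomer, interface_pka_shift=shift,
                              interchain_coupling=pairs)

    sampling = cfg.get("sampling", {})
    return RunConfig(
        model=monomer,
        dimer=dimer,
        flip_probs=flip,
        pH_grid=_parse_grid(sampling.get("ph_grid",
                                         {"start": 3.0, "stop": 8.0, "step": 0.5})),
        n_replicates=int(sampling.get("replicates", 5)),
        n_frames=int(sampling.get("frames", 10_000)),
        seed=int(sampling.get("seed", 42)),
        burn_in=int(sampling.get("burn_in", 500)),
        temperature=temperature,
        ref_pH_linkage=float(analysis.get("ref_ph_linkage", 3.0)),
        ref_pH_fraction=float(analysis.get("ref_ph_fraction", 7.5)),
        correlation_threshold=float(analysis.get("correlation_threshold", 0.3)),
        n_boot=int(analysis.get("n_boot", 1000)),
        subset=analysis.get("subset"),
        f_ref_grid=np.asarray(analysis.get("f_ref_grid",
                                           np.arange(0.1, 0.95, 0.1)), float),
        raw=cfg,
    )


def example_config() -> str:
    """A minimal self-describing YAML configuration."""
    return """\
sites:
  - {label: GluA, compartment: lumenal, pka_int: 5.3, flip_prob: 1.0}
  - {label: GluB, compartment: lumenal, pka_int: 4.6, flip_prob: 1.0}
  - {label: AspC, compartment: stromal, pka_int: 4.0, flip_prob: 0.1}
couplings:
  - {i: GluA, j: AspC, energy: -2.0}
dimer:
  interface_pka_shift: {GluA: -1.0}
  interchain_couplings:
    - {i: GluB, j: GluB, energy: 1.5}
sampling:
  ph_grid: {start: 3.0, stop: 8.0, step: 0.5}
  replicates: 5
  frames: 5000
  seed: 42
analysis:
  temperature: 298.15
  ref_ph_linkage: 3.0
  ref_ph_fraction: 7.5
  correlation_threshold: 0.3
  n_boot: 500
  subset: {compartment: lumenal}
"""
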