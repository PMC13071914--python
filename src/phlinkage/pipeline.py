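"""End-to-end orchestration: simulate -> titrate -> correlate -> linkage -> fraction.

Each stage is a pure function over the shared :class:`~phlinkage.io.RunConfig`
and the ensembles; `run_pipeline` chains them and writes one TSV/JSON bundle
per stage under the output directory.  All randomness flows from the config
seed, no stage mutates its inputs, and a rerun with identical inputs and seed
reproduces the bundle byte for byte (outputs carry no timestamps).  Every
bundle includes machine-readable provenance (config hash, seed, versions).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import (build_network, ensemble_correlation_times,
                          pairwise_correlation)
from .ensemble import ProtonationEnsemble
from .equilibrium import fraction_shift, fraction_uncertainty
from .io import RunConfig, write_occupancy
from .linkage import (bootstrap_profile, linkage_input_from_ensembles,
                      residue_decomposition, screen_key_residues)
from .sampling import sample_ensemble
from .titration import fit_hill, global_curve, residue_curve

STAGES = ("simulate", "titrate", "correlate", "linkage", "fraction", "report")
_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage refused to run (missing inputs, mismatched grids)."""


def _curve_rows(curve):
    return pd.DataFrame({
        "subject": curve.subject, "pH": curve.pH, "mean": curve.mean,
        "ci_lo": curve.ci_lo, "ci_hi": curve.ci_hi,
        "n_replicates": curve.n_replicates,
    })


def _profile_rows(profile):
    df = pd.DataFrame({
        "subject": profile.subject, "pH": profile.pH,
        "ddG_kcal_mol": profile.values,
    })
    df["ci_lo"] = profile.ci_lo if profile.ci_lo is not None else profile.values
    df["ci_hi"] = profile.ci_hi if profile.ci_hi is not None else profile.values
    return df


def config_hash(config: RunConfig) -> str:
    canonical = yaml.safe_dump(config.raw, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    stages=STAGES,
    ensembles: dict[str, ProtonationEnsemble] | None = None,
) -> dict:
    """Run the requested stages, writing one result bundle under ``out_dir``.

    ``ensembles`` may inject pre-loaded data (skipping ``simulate``); the
    linkage and fraction stages refuse to run without both monomer and dimer.
    Returns a dict of in-memory stage results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}; "
                            f"valid stages are {STAGES}")
    results: dict = {"ensembles": dict(ensembles or {})}
    ens = results["ensembles"]

    if ens:
        grids = {s: tuple(e.pH_grid) for s, e in ens.items()}
        if len(set(grids.values())) > 1:
            raise PipelineError(f"pH grids differ between systems: {grids}")

    if "simulate" in stages:
        flip_m = config.flip_probs
        ens["monomer"] = sample_ensemble(
            config.model, config.pH_grid, config.n_replicates, config.n_frames,
            seed=config.seed, flip_attempt_prob=flip_m,
            n_burn=config.burn_in, system="monomer")
        ens["dimer"] = sample_ensemble(
            config.dimer, config.pH_grid, config.n_replicates, config.n_frames,
            seed=config.seed + 1, flip_attempt_prob=np.tile(flip_m, 2),
            n_burn=config.burn_in, system="dimer")
        write_occupancy(ens, out / "occupancy.tsv", out / "sites.tsv")

    if "titrate" in stages:
        _require(ens, ("monomer",), "titrate")
        curves, fits = [], {}
        for system, e in sorted(ens.items()):
            policy = "average-chains" if system == "dimer" else "single-chain"
            for label in sorted(set(e.sites["label"])):
                c = residue_curve(e, label, chain_policy=policy,
                                  n_boot=config.n_boot, seed=config.seed)
                curves.append(_curve_rows(c))
                fit = fit_hill(c)
                fits[f"{system}:{c.subject}"] = {
                    "pka": fit.pka, "hill_h": fit.hill_h,
                    "pka_se": fit.pka_se, "hill_se": fit.hill_se,
                    "converged": fit.converged,
                    "low_confidence": fit.low_confidence, "reason": fit.reason}
            factor = 2.0 if system == "monomer" and "dimer" in ens else 1.0
            for subset in (None, {"compartment": "lumenal"}):
                g = global_curve(e, subset=subset, stoichiometry_factor=factor,
                                 n_boot=config.n_boot, seed=config.seed)
                g.subject = f"{system}:{g.subject}"
                curves.append(_curve_rows(g))
        pd.concat(curves, ignore_index=True).to_csv(
            out / "titration_curves.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        _dump_json(out / "hill_fits.json", fits)
        results["hill_fits"] = fits

    if "correlate" in stages:
        _require(ens, ("monomer",), "correlate")
        networks, taus = [], []
        map_dir = out / "correlation_maps"
        map_dir.mkdir(exist_ok=True)
        for system, e in sorted(ens.items()):
            maps = [pairwise_correlation(e, ph) for ph in e.pH_grid]
            ids = e.sites["site_id"].tolist()
            for cmap in maps:
                pd.DataFrame(cmap.matrix, index=ids, columns=ids).to_csv(
                    map_dir / f"{system}_pH{cmap.pH:g}.tsv", sep="\t",
                    float_format=_FLOAT_FMT)
            net = build_network(maps, e.sites,
                                threshold=config.correlation_threshold)
            net.edges.insert(0, "system", system)
            networks.append(net.edges)
            for ph in e.pH_grid:
                for ct in ensemble_correlation_times(e, ph):
                    taus.append({"system": system, "site_id": ct.site,
                                 "pH": ct.pH, "tau_frames": ct.tau_frames,
                                 "cutoff_lag": ct.cutoff_lag,
                                 "defined": ct.defined, "reason": ct.reason})
        pd.concat(networks, ignore_index=True).to_csv(
            out / "correlation_network.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        pd.DataFrame(taus).to_csv(out / "correlation_times.tsv", sep="\t",
                                  index=False, float_format=_FLOAT_FMT)
        results["network"] = networks

    if "linkage" in stages:
        _require(ens, ("monomer", "dimer"), "linkage")
        profiles = []
        for subset in (None, {"compartment": "lumenal"},
                       {"compartment": "stromal"}):
            boot = bootstrap_profile(
                ens["monomer"], ens["dimer"], ref_pH=config.ref_pH_linkage,
                temperature=config.temperature, subset=subset,
                n_boot=config.n_boot, seed=config.seed, per_residue=not subset)
            profiles.append(_profile_rows(boot.total))
            if not subset:
                results["linkage_total"] = boot
                for label in sorted(boot.residues):
                    profiles.append(_profile_rows(boot.residues[label]))
            elif subset["compartment"] == "lumenal":
                results["linkage_lumenal"] = boot
        inp = linkage_input_from_ensembles(ens["monomer"], ens["dimer"],
                                           config.temperature)
        _, lumenal_res = residue_decomposition(
            inp, config.ref_pH_linkage, subset={"compartment": "lumenal"})
        key = screen_key_residues(lumenal_res, threshold_kcal=1.0)
        pd.concat(profiles, ignore_index=True).to_csv(
            out / "ddg_profiles.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        _dump_json(out / "linkage_summary.json", {
            "ref_pH": config.ref_pH_linkage,
            "temperature_K": config.temperature,
            "subsets": ["all", "lumenal", "stromal"],
            "n_boot": config.n_boot, "seed": config.seed,
            "quadrature": "trapezoid on the measured grid"})
        _dump_json(out / "key_residues.json", {
            "subset": "lumenal", "threshold_kcal_mol": 1.0,
            "residues": [{"label": l, "max_abs_ddG_kcal_mol": v}
                         for l, v in key]})
        results["key_residues"] = key

    if "fraction" in stages:
        if "linkage_lumenal" not in results:
            raise PipelineError("fraction stage needs the linkage stage output "
                                "(lumenal ddG profile); run linkage first")
        prof = results["linkage_lumenal"].total
        maker = (fraction_uncertainty if prof.ci_lo is not None
                 else fraction_shift)
        curve = maker(prof, ref_pH=config.ref_pH_fraction,
                      f_ref_grid=config.f_ref_grid,
                      temperature=config.temperature)
        curve.table.to_csv(out / "monomer_fraction.tsv", sep="\t", index=False,
                           float_format=_FLOAT_FMT)
        _dump_json(out / "monomer_fraction_meta.json", {
            "ref_pH": curve.ref_pH, "subset": "lumenal",
            "temperature_K": curve.temperature,
            "fraction_convention": "fraction of chains in monomeric form"})
        results["fraction"] = curve

    if "report" in stages:
        _dump_json(out / "provenance.json", {
            "package": "phlinkage", "version": __version__,
            "numpy": np.__version__,
            "config_sha256_16": config_hash(config),
            "seed": config.seed,
            "temperature_K": config.temperature,
            "n_replicates": config.n_replicates,
            "n_frames": config.n_frames,
            "stages": list(stages),
        })
    return results


def _require(ens, systems, stage):
    missing = [s for s in systems if s not in ens]
    if missing:
        raise PipelineError(
            f"stage {stage!r} needs {missing} ensemble(s); provide them via "
            "the simulate stage or as inputs")


def _dump_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=float) + "\n")
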