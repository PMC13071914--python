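# phlinkage

Titration, protonation-correlation and Wyman-linkage analysis of constant-pH
protonation ensembles.

pH-sensing membrane proteins — the motivating case is a thylakoid
photoprotection sensor whose lumen-facing glutamates respond to lumen
acidification (pH ~7.5 → ~5.7) — couple the protonation of acidic residues
to an oligomerization equilibrium 2M ⇌ D.  Constant-pH simulations deliver
per-pH binary protonation records of the monomer and the dimer; this package
turns those records into the quantities that connect protonation to
association:

* **Titration curves** per residue and globally, with 68% replicate-bootstrap
  bands, and **Hill fits** `⟨x⟩(pH) = 1/(1+10^(h(pH−pKa)))` for pKa and
  cooperativity;
* **Protonation correlation networks** (phi coefficient per pH, |phi| ≥ 0.3
  edges, cross-compartment flags) and **protonation correlation times**
  (integrated ACF, `tau = 1/2 + Σ C(t)`);
* the **relative dimerization free energy** via the linkage relation

      ΔΔG(pH) = ln(10)·kT ∫_ref^pH [Q_D(u) − 2·Q_M(u)] du,

  with an exact per-residue additive decomposition, lumenal/stromal subset
  restriction and bootstrap bands;
* the **acidification-induced shift of the monomer fraction** under
  2M ⇌ D mass action, `f + 2κf² = 1` with `κ(pH) = κ_ref·e^(−ΔΔG/kT)`,
  parameterized by the reference-pH monomer fraction.

Because real constant-pH MD data are not reproducible at desk scale, the
package includes a first-class synthetic generator: an Ising-like model of
interacting titratable sites sampled by Metropolis Monte Carlo and solved
**exactly** by partition-function enumeration (factorized over coupling
components), which serves as the ground-truth oracle for every estimator.
See `docs/methods.md` for the model and all numerical choices.

## Worked example

The repository's `analysis/` drivers run a complete study on the bundled toy
pH-sensor fixture (16-site monomer, 32-site dimer with planted interface pKa
shifts on Glu55/Glu69/Glu173 and planted couplings; 5 replicates per pH):

```bash
cd analysis
python 01_simulate.py        # sample + verify against the exact oracle
python 02_titration.py       # titration curves and Hill fits
python 03_correlations.py    # networks and correlation times
python 04_linkage.py         # ddG(pH) profiles and per-residue screen
python 05_monomer_fraction.py
```

`02_titration.py` prints (monomer vs chain-averaged dimer):

```
residue        monomer pKa (h)       dimer pKa (h)
Glu55             5.19 (1.01)         3.90 (1.01)
Glu69             5.00 (1.00)         3.90 (1.00)
Glu78             6.20 (1.01)         6.21 (0.99)
Glu141            5.50 (1.00)         4.47 (0.47)
Glu173            6.30 (1.00)         4.80 (1.00)
Glu180            6.50 (1.00)         6.50 (1.00)
```

The three interface-shifted residues titrate 1.1–1.5 pH units lower in the
dimer; Glu141, coupled across the interface, keeps a similar midpoint but
turns strongly anticooperative (h = 0.47).  `04_linkage.py` then reports

```
ddG(pH 8) = -10.10 kcal/mol (exact -10.14); lumenal-only -10.29
oracle check: max |sampled - exact| = 0.054 kcal/mol
lumenal residues contributing >= 1 kcal/mol:
  Glu173   max |ddG_i| = 4.05 kcal/mol
  Glu55    max |ddG_i| = 3.39 kcal/mol
  Glu69    max |ddG_i| = 2.87 kcal/mol
```

i.e. the dimer gains stability as pH rises (interface interactions stabilize
the deprotonated acids), and the 1 kcal/mol screen recovers exactly the
planted residues.  Finally `05_monomer_fraction.py` converts the
lumenal-only profile (re-anchored at pH 7.5) into fraction shifts:

```
 f_ref   f(5.75)    shift           68% band
  0.20     0.692   +0.492 [0.687, 0.696]
  0.50     0.943   +0.443 [0.941, 0.944]
  0.80     0.990   +0.190 [0.990, 0.990]
```

Acidification to pH 5.75 pushes this fixture strongly toward monomers at
every assumed reference fraction.  Small result tables land in `results/`.

A `phlink` CLI wraps the same pipeline for user-supplied configurations and
occupancy tables (`phlink example-config`, then
`phlink run --config cfg.yaml --out results/`); stages are
`simulate | titrate | correlate | linkage | fraction | report`, exit codes
0/2/3 for success/validation/numerical failure.

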