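# notchcis

Kinetic modelling and single-cell analysis of Notch–ligand **cis**
interactions and their modulation by Fringe glycosyltransferases.

Notch receptors and their DSL ligands (Dll1/Delta, Jag1/Serrate) interact
not only between neighbouring cells (*trans*-activation) but also within
the same cell, where receptor and ligand mutually inactivate one another
(*cis*-inhibition). Which of a cell's components survive this mutual
titration determines its *signaling state* — whether it can send, receive,
both (with different ligands), or neither — and Fringe enzymes re-weight
the interactions ligand-specifically. This package is for quantitative
biologists who want to model that system, analyse surface-availability
measurements against it, and explore its tissue-level consequences.

It provides:

* **`notchcis.kinetics`** — the cis-inactivation model. Reactions
  N + D ⇌ [ND] → ∅ with production and turnover give, under a
  quasi-steady-state reduction with lumped constant
  kc = (kC₋ + kI)/(kC₊·kI), the closed form

      N_ss = (βN/γN) / (1 + D/(kc·γN)),

  so the ligand level kc·γN halves available receptor. Exact steady-state
  solvers for one or several competing cis-ligands, trans signal rates,
  and multiplicative Fringe presets (`none`, `lfng`, `mfng`, `rfng`,
  Drosophila `fng`).
* **`notchcis.synthetic`** — generators for every pipeline input, with
  known ground truth: per-cell availability tables over 4-epiTc induction
  levels, saturation-binding calibration curves (signal = a·D/(D+K)),
  ligand-dilution time-lapse traces, and multi-channel cell images with
  pixel-exact label masks.
* **`notchcis.imaging`** — cytoplasm-stain segmentation, local-median
  background subtraction, per-cell mean fluorescence, area and isolation
  gates.
* **`notchcis.fitting`** — log-binned median profiles with bootstrap CIs,
  effective-total-ligand and uninduced normalisations, saturation and
  cis-inhibition fits (avail = bg + A/(1 + L/L50)), per-bin Wilcoxon
  rank-sum comparisons, and reporter-onset (t_on) detection.
* **`notchcis.states` / `notchcis.boundary`** — the signaling-state
  classifier, the inter-state signaling graph (no self-edges, no cycles
  for the canonical strong-cis states), and a two-phase lattice model of
  dorsal–ventral boundary formation in the fly wing disc.

See `docs/methods.md` for the model, parameter defaults and numerical
choices.

## Worked example

Generate a synthetic availability experiment (2000 cells across four
induction levels) and fit the cis-inhibition curve to the single-cell
points:

```python
from notchcis.synthetic import (GeneratorConfig, generate_availability_dataset,
                                half_inhibition_total_ligand)
from notchcis.fitting import fit_cis_inhibition

cfg = GeneratorConfig(n_cells_per_level=500, seed=42)
table = generate_availability_dataset(cfg)          # 2000 cells, 4 doses
fit = fit_cis_inhibition(table.total_ligand_fluor, table.availability_fluor)
truth = half_inhibition_total_ligand(cfg)

print(f"fitted A   = {fit.amplitude:7.1f}  (availability at zero ligand)")
print(f"fitted L50 = {fit.L50:7.1f}  (half-inhibition, fluorescence units)")
print(f"fitted bg  = {fit.background:7.1f}")
print(f"true  T50  = {truth:7.1f}  -> error {100*abs(fit.L50/truth-1):.1f}%")
```

prints

```
fitted A   =  1002.0  (availability at zero ligand)
fitted L50 =  1062.5  (half-inhibition, fluorescence units)
fitted bg  =    43.1
true  T50  =  1050.0  -> error 1.2%
```

A is the free-receptor signal of uninduced cells, L50 the effective
total-ligand level at which availability halves (the fluorescence
analogue of kc·γN), and bg the additive assay background; the fitted
half-inhibition lands within ~1% of the generator's ground truth.

The same pipeline is scriptable from the shell:

```sh
notchcis generate assay --seed 42 --out assay.csv
notchcis fit cis --in assay.csv --out fit.json
notchcis states graph --out edges.csv
notchcis boundary run --out boundary/
```

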