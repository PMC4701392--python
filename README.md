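# crystfold

Equilibrium-unfolding, aggregation-kinetics and interface-geometry analysis
for oligomeric lens crystallins and similar multi-subunit proteins.

δ-crystallin, the major structural protein of avian and reptile lenses, is a
homotetramer (a dimer of dimers) homologous to argininosuccinate lyase.  Its
chemical denaturation proceeds through subunit dissociation and partially
folded monomeric intermediates, and the partly unfolded intermediates are
prone to aggregate.  `crystfold` packages the quantitative analyses such a
folding study needs:

* **spectra** — reduce raw measurements to scalar observables: average
  emission wavelength (AEW) of tryptophan fluorescence, integrated ANS band
  area, mean residue ellipticity ([θ] = θ·MRW / (10·d·c)) and specific
  argininosuccinate-lyase activity from A240 traces (ε = 2440 M⁻¹cm⁻¹).
* **unfolding** — evaluate and globally fit linear-extrapolation-method
  (LEM) equilibrium models: the two-state Santoro–Bolen form

  y(D) = [(y_n + m_f·D) + (y_u + m_u·D)·e^(−(ΔG⁰−m·D)/RT)] / [1 + e^(−(ΔG⁰−m·D)/RT)]

  and its sequential three-/four-state generalisation
  (N ⇌ I₁ ⇌ I₂ ⇌ U with cumulative free energies ΔG₁, ΔG₁+ΔG₂,
  ΔG₁+ΔG₂+ΔG₃), with midpoints [D]₁/₂ = ΔGᵢ⁰/mᵢ, state populations,
  AICc/F-test model selection, and multi-start bounded least squares with
  the midpoint ordering enforced during optimisation.
* **aggregation** — fit turbidity (A360) rises with
  y(t) = y₀ + Σᵢ yᵢ(1 − e^(−kᵢt)) (one or two phases) or a line, select the
  kinetic model by AICc, and compute thioflavin-T fold-enhancement series.
* **geometry** — parse PDB structures/trajectories (via Biopython), track
  Cα–Cα distances of interface residue pairs (e.g. the diagonal K315–K315
  pair, the R302–E330 salt bridge) across frames, fit linear separation
  rates, and list cross-chain N/O contacts within a hydrogen-bond cutoff.
* **synthetic** — generate every input with known ground truth: model
  curves with Gaussian noise, red-shifting Gaussian emission spectra,
  exponential turbidity traces, toy tetramers and separating trajectories.
* **pipeline / CLI** — config-driven end-to-end runs with JSON reports:
  `crystfold fixtures | unfold | aggregate | structure`.

## Worked example

Recover the published thermodynamics from synthetic replicate experiments
(50 noisy AEW curves each, σ = 0.2 nm, fitted jointly):

```python
from crystfold.recovery import four_state_recovery, two_state_recovery

two = two_state_recovery(range(1, 51))
print(f"two-state (urea, T<->M): dG0 = {two['dG0']:.2f} kcal/mol, "
      f"m = {two['m']:.2f} kcal/mol/M, midpoint = {two['midpoint']:.2f} M")
four = four_state_recovery(range(1, 51))
print(f"four-state (GdmCl, M<->I1<->I2<->U): midpoints = "
      f"{four['midpoint1']:.2f}, {four['midpoint2']:.2f}, {four['midpoint3']:.2f} M; "
      f"total dG = {four['dG_total']:.1f} kcal/mol")
```

prints

```
two-state (urea, T<->M): dG0 = 6.55 kcal/mol, m = 3.83 kcal/mol/M, midpoint = 1.71 M
four-state (GdmCl, M<->I1<->I2<->U): midpoints = 0.63, 2.11, 3.85 M; total dG = 12.8 kcal/mol
```

The two-state run emulates the urea-driven tetramer→monomer dissociation of
the K315A mutant (true ΔG⁰ = 6.5 kcal/mol, m = 3.8, midpoint 1.7 M); the
four-state run emulates GdmCl unfolding of the dissociated monomer through
two intermediates (true midpoints 0.62, 2.17 and 3.87 M, total
ΔG⁰ = 12.8 kcal/mol).  Recovered values land on the generating truth within
the sampling error of the protocol.

For a file-based tour, `crystfold fixtures --out demo/` writes synthetic
curve/trace/trajectory files plus ready-made configs, and
`crystfold unfold --config demo/unfold_four_state.yaml --out demo/` writes a
JSON fit report.

## Layout

```
src/crystfold/
  spectra.py      reductions and domain types (spectra, curves, CD, activity)
  unfolding.py    LEM models, state populations, global fitting, model selection
  aggregation.py  turbidity kinetics and ThT enhancement
  geometry.py     PDB parsing, pair-distance tracks, interface contacts
  synthetic.py    ground-truth data generators
  recovery.py     parameter-recovery benchmark protocols
  io.py           CSV interfaces with #key=value headers
  pipeline.py     config-driven orchestration with JSON reports
  cli.py          click CLI (fixtures / unfold / aggregate / structure)
docs/methods.md   modelling assumptions, numerical choices, limitations
```
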