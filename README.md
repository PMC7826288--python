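# teloforce

Single-molecule magnetic-tweezers analysis of telomere mechanics and
TRF1 dynamics.

Telomeres — the TTAGGG-repeat ends of human chromosomes — are organized
and protected by the shelterin protein TRF1, which binds double-stranded
telomeric DNA as a homodimer and compacts it into loops. Magnetic
tweezers make this machinery measurable one molecule at a time: a
telomere (or a designed telomeric hairpin) is tethered between a glass
surface and a superparamagnetic bead, and the bead height reports the
tether extension while the magnets apply 0–22 pN. `teloforce`
implements the complete analysis chain for four such assays, together
with a synthetic trace generator with exact ground truth so every stage
is testable at desk scale:

1. **Telomere length (TL) by force–extension.** At force *F* the
   relative extension of dsDNA follows the extensible worm-like chain
   (WLC),
   `x/Lc = 1 − ½·√(kBT/(F·Lp)) + F/S`,
   with `Lp = 51.1 nm` and `S = 1006 pN` at ~100 mM NaCl. At the 17 pN
   reference this gives 0.33 nm per base pair, converting extensions to
   TL in bp.
2. **Rupture kinetics of TRF1-compacted loops (force jump).** Loop
   rupture at a test force follows Bell–Evans kinetics,
   `k(F) = k0·exp(F·x†/kBT)`; regression of `ln k` on *F* yields the
   zero-force dissociation rate `k0` and activation distance `x†`.
   Loop-size distributions (ΔL) are fitted as 1-D Gaussian mixtures, and
   the loop number N vs ΔL relation is quantified by zero/first/second-
   order Pearson partial correlations.
3. **Strand separation of a telomeric hairpin.** A 169-bp hairpin stem
   with 23 TTAGGG repeats and two non-binding spacers (TGG at stem
   position 79, CGTC at 142) is unzipped above its critical force; bound
   TRF1 dimers block the fork and produce pauses. Step fitting on
   zero-corrected traces (released ssDNA converted to bp with the
   Marko–Siggia WLC, `Lp = 0.87 nm`, `0.69 nm/nt`) gives pause dwell
   times, ~10–12 bp sub-steps, and per-bp residence maps.
4. **Two-state fork hopping near the critical force.** A Gaussian
   two-state HMM decodes forward/backward states; across forces the open
   probability follows the Boltzmann relation
   `P_o(F) = 1/(1 + exp((F½ − F)·Δx/kBT))`, and `ΔG = F½·Δx/kBT` gives
   the strand-separation free energy, with and without TRF1.

## Layout

- `src/teloforce/` — the library (polymer models, generators, step
  fitting, HMM, kinetic fits, TL pipeline, CLI).
- `analysis/01…06_*.py` — numbered narrative analyses; each writes its
  tables under `results/` and prints what it found.
- `scripts/acceptance.py` — recomputes the headline quantities (below).

## Worked example

```python
from teloforce import synth, steps, kinetics
from teloforce.replica import _ramp_protocol
from teloforce.tl import measure_tl

# simulate a 2.5-kb telomere with one 640-bp TRF1 loop and measure it
spec = synth.TelomereMoleculeSpec(tl_bp=2500, noise_sd=0.0,
                                  loops=[synth.LoopEvent(640.0)])
trace = synth.simulate_force_extension(spec, _ramp_protocol(), seed=4)
print(measure_tl(trace).tl_bp)            # -> 2498.7 (bp at 17 pN)

# force-jump assay: extract the rupture events at F_test
spec = synth.TelomereMoleculeSpec(
    tl_bp=2500, loops=[synth.LoopEvent(250.0), synth.LoopEvent(640.0)])
jump = synth.simulate_force_jump(spec, f_test=8.0, t_rest=2.0,
                                 t_test=40.0, n_cycles=4, seed=11)
for ev in steps.extract_ruptures(jump)[:2]:
    print(round(ev.delta_l_bp), round(ev.dwell_s, 2))
# -> 256  7.13
# -> 635  0.29
```

The first number is the loop size released by each rupture, converted
from the extension leap with the force-dependent WLC factor at 8 pN; the
second is the dwell time since the jump to the test force (first event)
or since the previous rupture.

Command-line equivalents:

```
teloforce simulate --config cfg.yaml --out traces/
teloforce analyze traces/ --out results/
teloforce fit --kind bell_evans --table results/ruptures.tsv --out fit.txt
teloforce replicate --seed 1 --out results/
```

Running the numbered analyses end to end (`python analysis/0N_….py`)
prints, among others:

```
dsDNA extension per bp at 17 pN: 0.3341 nm/bp (rounds to 0.33)
physiological TRF1 dimer concentration: 21.6 nM (12.2-43.7 nM)
measured 200 synthetic telomeres: 2.51 +/- 0.89 kb (range 0.53-5.15 kb)
Bell-Evans: k0 = 0.0394 1/s, x-dagger = 0.833 nm, zero-force dwell 1/k0 = 25.4 s
[25nM] tau = 0.344 +/- 0.023 s (true 0.36, n = 223, histogram R^2 = 0.972)
[40nM] tau = 1.747 +/- 0.161 s (true 1.71, n = 118, histogram R^2 = 0.966)
spacer at bp 79: occupancy 0.0004 s/bp vs flanking peak 0.0470 s/bp (ratio 0.01) -> valley
dG with TRF1: 62.4 kBT ... dG without TRF1: 49.5 kBT ... ddG: 12.9 kBT
```

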