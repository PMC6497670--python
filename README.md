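# deerdock

Tools for determining C2-symmetric membrane-protein dimer architectures from
PELDOR/DEER dipolar spectroscopy, plus the stochastic heterodimer-mixing
transport model used to probe functional coupling between protomers.

The package covers the full computational chain:

- **`structures`** — PDB I/O (nm internally, Å at file boundaries), rigid
  transforms, exact C2 dimer assembly from four pose parameters
  (α, β, x, y; γ = 0, z = 0), Cα clash/contact tests, and Shrake–Rupley
  buried surface area.
- **`spin_labeling`** — spin-label position ensembles per labeled residue
  (uniform-shell stand-in for a rotamer library, or a user-supplied rotamer
  table in the local backbone frame) and inter-site / inter-protomer
  distance distributions.
- **`deer_forward`** — angle-averaged dipolar kernel (Fresnel closed form,
  Gauss–Legendre quadrature cross-check), form factors with modulation
  depth, exponential intermolecular background (apply / remove / fit),
  and forward traces from a C2 pose including the per-rotamer-pair signal
  matrix.
- **`deer_invert`** — non-negative Tikhonov inversion with second-derivative
  smoothing, L-curve corner selection of the regularization parameter, and
  a modulation-depth scan.
- **`dimer_dock`** — exhaustive (α, β, x, y) grid search against
  mean-distance restraints with clash/contact filtering and a radial
  pre-cull, Nelder–Mead local refinement, and a time-domain contact-sweep
  mode that slides the second protomer to the touching position and scores
  χ² against form factors.
- **`ensemble_reweight`** — maximum-entropy (BioEn-style) reweighting of
  rotamer-pair weights: minimize θ·S_KL + χ²/2 in log-weight coordinates,
  L-curve selection of θ, and minimum-total-χ² conformer selection.
- **`transport_mixing`** — binomial dimer-class fractions, the quadratic
  mixing-rate model, initial-rate estimation from uptake time courses, and
  closed-form fitting of the relative heterodimer activity.
- **`synthetic_data`** — deterministic toy protomers (ideal Cα helices),
  ground-truth dimer scenarios with noisy traces and restraint tables, and
  uptake datasets; everything the test suite needs is generated on the fly.

## Command line

```bash
# write a self-contained synthetic bundle (PDB, traces, restraints, manifest)
deerdock simulate --seed 1 --out bundle/

# invert a trace to P(r) (CSV + JSON sidecar with moments)
deerdock invert --trace bundle/trace_A5.dat --background 0.1 \
    --depth 0.35 --rmin 1 --rmax 14 --out pr.csv

# distance-restraint C2 docking with refinement
deerdock dock --pdb bundle/protomer.pdb --restraints bundle/restraints.csv \
    --xy-range 3.5 --out dock.json

# maximum-entropy reweighting of rotamer-pair weights
deerdock reweight --model model.json --theta auto --out weights.json
```

## Conventions

- Internal unit is nm everywhere; Å only in PDB files and reported surface
  areas (Å²). Times in µs, rates in µs⁻¹; uptake in nmol·mg⁻¹, minutes.
- The membrane normal is +z. Pose rotations are active and right-handed:
  α about z, then β about y, then the (x, y) translation; the dimer partner
  is the 180° z-rotation of the placed protomer.
- Distance data cannot distinguish a pose from its z-mirror partner
  (α+180°, 180°−β, x, −y); `dimer_dock.pose_equivalents` enumerates the pair.
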