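# fibrilmetrics

Quantitative analysis of amyloid fibril architecture, written for
structural biologists working on light-chain (AL) amyloidosis and related
cross-β fibrils. The package covers the desk-scale computations that
accompany a single-particle fibril study:

- **Worm-like-chain mechanics** — measure contour length *L* and
  end-to-end distance *D* of traced fibrils and fit the surface-equilibrated
  2D worm-like-chain relation

  ⟨D²⟩ = 4PL·[1 − (2P/L)(1 − e^(−L/2P))]

  to estimate the persistence length *P*, converting to the bending
  rigidity *B* = *P·k*B·*T*.
- **Helical symmetry** — relate the per-subunit rise (Å) and signed twist
  (°) of a protofilament to pitch and cross-over distance
  (pitch = rise·360/|twist|), build stacks under the screw operation,
  recover (rise, twist) from an atomic model by Kabsch superposition of
  consecutive layers, and map inter-layer residue contacts and salt
  bridges.
- **Sequence profiles** — Kyte–Doolittle hydropathy, per-residue
  amyloidogenicity scans (packing-density and AGGRESCAN-style scales),
  ingestion of external predictor output (WALTZ, TANGO, FoldAmyloid,
  Aggrescan, AmylPred), the 0–5 consensus amyloid score, and
  germline-vs-patient mutation listing with charge/burial/CDR/cavity
  annotations.
- **Conformational comparison** — β-strand assignment from backbone
  dihedrals, residue-level strand-registry overlap, the disulfide-anchored
  rotational switch (parallel vs antiparallel orientation of the two
  segments flanking the conserved Cys22–Cys89 bond), and disulfide
  geometry.
- **Cavity detection** — occupancy-grid flood fill that finds sealed
  interior voids, their volumes, lining residues and polarity class.
- **Synthetic data** — generators for every input: seeded 2D worm-like
  chain traces, an idealised flat β-arch protomer layer, sealed cavity
  phantoms with analytic void volumes, ideal-dihedral peptide backbones,
  and a germline/patient sequence pair with ten defined substitutions.

## Worked example

```python
import fibrilmetrics as fm

traces = fm.generate_trace_ensemble(6.7, 124, (1.0, 8.0), seed=7)
model = fm.WormLikeChainModel.from_traces(traces, temperature_k=300.0)
res = model.fit(n_bootstrap=1000, seed=7)
print(res.summary())
```

```
Worm-like-chain persistence length fit
==============================================
n fibrils                     124
temperature                 300.0 K
persistence length P        6.191 um
  fit SE                    0.442 um
  bootstrap SE              0.864 um  (n=1000)
  95% CI             [4.826, 8.142] um
bending rigidity B      2.564e-26 N m^2
  SE                    3.579e-27 N m^2
```

The ensemble was simulated at a true persistence length of 6.7 μm; the
fit recovers 6.19 μm for this seed, with a least-squares standard error of
0.44 μm and a fibril-resampling bootstrap SE of 0.86 μm (the bootstrap is
the more honest uncertainty for 124 fibrils — see `docs/methods.md`). The
bending rigidity follows as B = P·kB·T at 300 K, here 2.56×10⁻²⁶ N m².

Helical geometry is one call:

```python
pitch, crossover, hand = fm.pitch_and_crossover(fm.HelicalSymmetry(rise=4.8, twist=-0.58))
# pitch = 2979.3 A (298 nm), crossover = 1489.7 A, left-handed
```

A command-line interface mirrors the library
(`fibrilmetrics mechanics fit --traces traces.csv`,
`fibrilmetrics helix build|analyze`, `fibrilmetrics profile`,
`fibrilmetrics compare`, `fibrilmetrics cavities`, and
`fibrilmetrics run config.yaml` for the full pipeline).

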