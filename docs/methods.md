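# Methods

This note documents the models, numerical choices and known limitations of
fibrilmetrics, in the spirit of the methods documentation of statsmodels or
msprime: it states what each computation assumes and what the synthetic
generators do and do not emulate. No empirical number quoted here comes
from anywhere other than the package's own tests and scripts.

## Worm-like-chain mechanics

**Model.** A fibril deposited and equilibrated on a surface is treated as
a two-dimensional worm-like chain: the tangent angle θ(s) along arc length
s performs Brownian motion with ⟨(θ(s)−θ(0))²⟩ = s/P, where P is the
persistence length. The tangent autocorrelation is then
⟨cos Δθ⟩ = e^(−s/2P) — note the 2P, the 2D (surface-equilibrated)
convention — and the mean squared end-to-end distance of a chain of
contour length L has the closed form

    <D²> = 4PL · [1 − (2P/L)(1 − e^(−L/2P))].

Limits: D² → L² as L/P → 0 (rigid rod) and D² → 4PL as L/P → ∞
(2D random coil). The implementation uses `expm1` so the rigid limit is
evaluated without cancellation. The bending rigidity follows from
B = P·kB·T with kB = 1.380649×10⁻²³ J/K and T defaulting to 300 K;
micrometres are converted to metres in exactly one place to avoid
10⁶-scale mistakes.

**Estimation.** One (L, D) observation per fibril, no binning; D² is
regressed on L by unweighted nonlinear least squares (`scipy.optimize.curve_fit`),
initialised at P₀ = max(D²)/(4·max L) clipped to [0.01, 100] μm and
bounded in [10⁻⁶, 10⁴] μm. A fit pinned at the upper bound indicates
effectively straight fibrils (the rigid limit carries no information about
P) and is flagged on the results object and in `summary()`. Two
uncertainties are reported, because it is not obvious which one a given
published "±" refers to: the curvature-based least-squares SE, and a
seeded nonparametric bootstrap over fibrils (default 1000 resamples).

**Uncertainty honesty.** The per-fibril D² fluctuation of a worm-like
chain is large: at L = P the relative SD of D² is ≈ 13% (the package's
tests verify the simulator's Var(D²) against an independent oracle, a
Monte-Carlo evaluation of the exact Gaussian four-point tangent
correlator). Propagated through the fit, an ensemble of 124 fibrils with
contour lengths of a few μm yields a replicate-to-replicate SD of the
fitted P of roughly 0.8–0.9 μm at P = 6.7 μm. A coverage demand such as
"within ±0.5 μm in ≥ 90% of replicates" would require a replicate SD
≤ 0.30 μm, i.e. roughly ten times more fibrils; the corresponding test in
the suite states this expectation at full strength and fails for this
reason, not because of an implementation defect. The single-ensemble
least-squares SE (≈ 0.4–0.6 μm at these conditions) is systematically
smaller than the replicate SD because the residuals are heteroscedastic.

The nonlinear estimator also carries a small-sample bias of order +2% at
n = 124 when the length distribution concentrates in the rigid regime
(lengths ~1–8 μm at P = 6.7); with fibrils spanning a couple of
persistence lengths (2–12 μm) the bias falls near +1%. The bias test
therefore evaluates the estimator at the better-conditioned design.

**Generator.** `generate_wlc_trace` draws independent Gaussian tangent
increments of variance step/P per segment and integrates them to a
polyline of exactly round(L/step) equal segments (so the realised contour
length is the nearest multiple of the step). The default step of 0.02 μm
resolves P/50 even for the stiffest chains accepted; the constructor
rejects steps coarser than P/50. Default ensemble conditions are 124
fibrils, P = 6.7 μm, contour lengths uniform in 1–8 μm — an ensemble
size and stiffness typical of negative-stain TEM measurements of
patient-derived fibrils. The generator emulates equilibrated 2D traces
only: no projection from 3D, no tracing noise, no stain or ice artefacts,
no length-dependent selection of "well-resolved" fibrils. Passing tests
therefore validate the estimator under ideal sampling, not the tracing
step of a real experiment.

## Helical symmetry

A protofilament is a stack of protein layers related by a screw
operation: rotation by the twist (degrees, signed) about the fibril axis
plus translation by the rise (Å) along it. The axial coordinate is z by
convention; imported models can be re-aligned with `align_to_axis`, which
fits the screw axis rather than trusting the deposited orientation. Twist
sign: negative = left-handed. The type admits twist = 0 (a pure
translation, infinite pitch) so that degenerate stacks remain
constructible; `pitch_and_crossover` returns `inf` with handedness
"none" in that case.

`estimate_symmetry_from_model` superposes each consecutive chain pair by
the Kabsch algorithm, converts the rotation matrix to an axis–angle via
`scipy.spatial.transform.Rotation`, orients the axis so the rise is
positive, and reads the signed twist as the projection of the rotation
vector on that axis; per-pair values are averaged and the superposition
RMSD is reported. The axis point is recovered from the least-squares
solution of (I − R)a = t⊥ constrained to the plane a·û = 0. A pure
translation (|rotation| < 10⁻¹²) takes the translation direction as the
axis.

Contacts: residue pairs are reported when any two heavy atoms from
different residues come within the cutoff (default 4.5 Å, the common
heavy-atom contact convention), annotated by layer offset canonicalised
to ≥ 0. A salt bridge is flagged when an Arg/Lys side-chain nitrogen and
an Asp/Glu side-chain oxygen are within 4.0 Å. Width is reported either
as the maximal projected atom-centre extent or with the vdW radii of the
extreme pair added ("surface" mode); a density-map width is expected to
agree with the surface mode only approximately.

The synthetic β-arch layer is deliberately idealised — flat (all z
equal), C-alpha spacing ≈ 3.8 Å along a straight–turn–straight path, with
in-plane N/C pseudo-atoms. It exercises stacking, symmetry estimation and
contact mapping exactly, but has no side chains, no real β-arch hydrogen
bonding and no height modulation, so tests built on it do not probe
side-chain packing.

## Sequence profiles

Hydropathy uses the Kyte–Doolittle scale with a centred sliding window
(default window 1, i.e. raw per-residue values; windows are truncated at
the termini). The consensus amyloid score is the per-residue count (0–5)
of five predictors marking the residue. WALTZ and TANGO are
statistical-mechanics predictors that this package does not reimplement;
their per-residue outputs are ingested from two-column TSV files with the
documented hit rules (strictly above 0.00 for both; FoldAmyloid above
21.4 in runs of ≥ 5; Aggrescan above −0.02; AmylPred consensus flag).
De-novo scans are provided for the two scale-based predictors
(packing-density scale, threshold 21.4, 5-residue window, run ≥ 5;
AGGRESCAN a3v scale averaged over 5 residues against −0.02, run ≥ 5 per
the original hot-spot convention — note the ingestion rule for Aggrescan
TSVs applies the plain threshold without the run requirement, following
the rule as usually quoted for per-residue output). Exact reproduction of
any specific published predictor run is not expected: predictor versions
and parameters vary, and the packaged scale values could not be
re-verified against the original publications at build time.

Mutations are listed by direct comparison of equal-length, identically
numbered sequences (alignment is the caller's responsibility), and
`apply_mutations` refuses a substitution whose stated wild-type residue
disagrees with the sequence — a cheap guard against numbering-convention
slips. Annotations: side-chain formal charge at pH 7 (His neutral);
burial by a neighbour-count proxy (≥ 12 C-alpha atoms of other residues
within 10 Å of the residue's C-beta, C-alpha for Gly — counting C-alphas
keeps the proxy meaningful for backbone-only models); CDR membership from
caller-supplied ranges (no numbering scheme is imposed); cavity lining
from the cavity finder's lining lists.

The packaged germline template is synthetic: a reconstructed λ-type
variable-region placeholder assembled so that the conserved disulfide
cysteines (22, 89), the ordered-core boundaries (15, 105) and the
wild-type residues at the ten documented mutation positions are all
honoured under 1-based mature-chain numbering. It is suitable for
exercising the mutation machinery, not for biological inference about any
real germline allele.

## Conformational comparison

β-strand assignment uses a backbone-dihedral box: φ ∈ [−180°, −45°] and
ψ ∈ [45°, 180°] ∪ [−180°, −170°] (the extended region wraps through
±180°), configurable in source; maximal runs of ≥ 2 assignable residues
become strands. Chain breaks (peptide C–N > 2.0 Å) and residues missing
backbone atoms interrupt runs; terminal residues lack φ or ψ and are
never assigned. This is a deliberately simple heuristic — no
hydrogen-bond pattern analysis (DSSP-style) — adequate for comparing
strand registries between two states of the same sequence.

Segment orientation is the first principal component of the segment's
C-alpha coordinates, sign-oriented N→C by the first-to-last vector
(the plain endpoint vector is available as an option); the angle between
two segments lies in [0°, 180°], classified parallel below 90° and
antiparallel at or above. The rotational switch between a native and a
fibril conformation is reported for the two disulfide-flanking segments
(defaults 16–23 and 86–93) as the pair of angles, the two classifications
and a boolean switch flag. The parallel/antiparallel operationalisation
as a vector angle is this package's own; a pictorial definition admits
alternatives.

Disulfide geometry: Sγ–Sγ distance, bonded iff within [1.8, 2.5] Å — a
window around the 2.05 Å canonical S–S bond wide enough for coordinate
error at ~3 Å resolution.

## Cavity detection

Occupancy-grid flood fill: voxels (default spacing 0.5 Å, accepted range
0.2–1.5 Å) within vdW + probe (Bondi radii C 1.70, N 1.55, O 1.52,
S 1.80 Å; probe default 1.4 Å, water) of any heavy atom are occupied;
free voxels are labelled by 6-connectivity (deterministic, no diagonal
leakage); components touching the padded grid boundary are exterior; the
rest are cavities if ≥ 20 ų (default), sorted by volume and labelled
A, B, C… Volume is voxel count × spacing³, which over-estimates convex
voids slightly at coarse spacing and converges monotonically as the grid
is refined — the phantom tests check both the 15% accuracy at 0.5 Å and
the monotone error decrease over 1.0 → 0.5 → 0.25 Å.

Lining residues have any heavy atom within 4.5 Å of a cavity voxel
centre; the polar-lining fraction counts N/O atoms among lining
side-chain atoms (S counts apolar, so a disulfide lining reads
hydrophobic), and ≥ 0.5 classifies hydrophilic. A cavity with no lining
side-chain atoms is classified "unknown".

The cavity phantom places concentric Fibonacci-sphere shells of
pseudo-atoms with inner radius void_radius + vdW + probe, so the
probe-free interior has the prescribed analytic volume 4/3·π·r³;
atom spacing is capped at 1.5 Å, which guarantees the shell is sealed
against a 1.4 Å probe. An optional cylindrical channel along +x vents
the void to the exterior for negative controls.

## Pipeline and reproducibility

Every generator and every stochastic fit takes an explicit integer seed
(default 42). The pipeline validates all input paths before running any
stage, executes stages in the fixed order mechanics → helix → profile →
compare → cavities, records package version and seed in the JSON report,
writes keys sorted so reruns diff cleanly, and collects stage failures
under an `errors` section rather than aborting later stages.

Problem sizes used by the test suite and the acceptance script — 124
fibrils per ensemble, 50 replicate ensembles, 10⁴-trace moment checks,
12–91-residue synthetic layers, ~7000-atom phantoms on ≤ 0.25 Å grids —
were chosen as the smallest sizes at which the statistical checks have
meaningful power; all run on a single CPU in a few minutes.

## Known limitations

- The mechanics module is strictly 2D; no 3D worm-like-chain variants,
  tip-tracking kinetics or AFM height analysis.
- No density-map handling (no MRC/FSC), no micrograph simulation, and no
  helical reconstruction — the package starts from traces, sequences and
  atomic coordinates.
- Strand assignment is dihedral-only; structures with distorted but
  hydrogen-bonded strands will be under-assigned.
- The burial proxy is a contact count, not solvent-accessible surface
  area; it is calibrated for classification, not for quantitative RSA.
- Predictor scale values are packaged as transcribed; consult the
  original predictor publications before drawing biological conclusions
  from de-novo scans.
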