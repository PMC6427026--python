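"""Synthetic inputs for every stage of the pipeline.

The generators here emulate the experimental observables the analysis
modules consume: surface-equilibrated 2D worm-like-chain fibril traces,
an idealised flat beta-arch protomer layer, sealed-shell cavity phantoms
with a known void volume, ideal-dihedral peptide backbones, and a
germline/patient sequence pair carrying a defined set of substitutions.

Everything is deterministic under an explicit integer seed (default 42).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConstructionError, MutationMismatchError, ParameterError
from .mechanics import FibrilTrace
from .scales import ONE_TO_THREE, vdw_radius
from .structure import AtomicModel, Layer

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

# ---------------------------------------------------------------------------
# Worm-like-chain traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WLCParams:
    """Parameters of a simulated 2D worm-like-chain trace (lengths in um).

    ``step`` must resolve the persistence length (step <= P/50) for the
    discrete tangent walk to approximate the continuous chain.
    """

    persistence_length: float
    total_length: float
    step: float = 0.02
    seed: int = 42

    def __post_init__(self):
        if self.persistence_length <= 0:
            raise ParameterError("persistence_length must be > 0")
        if not (0 < self.step <= self.total_length):
            raise ParameterError("need 0 < step <= total_length")
        if self.step > self.persistence_length / 50.0:
            raise ParameterError(
                "step must be <= persistence_length/50 for discretization validity")


def generate_wlc_trace(params: WLCParams, fibril_id: str = "sim") -> FibrilTrace:
    """Simulate one surface-equilibrated 2D worm-like-chain trace.

    The tangent angle performs a Gaussian random walk with increment
    variance ``step / P`` per segment, which gives the 2D tangent
    autocorrelation ``<cos(theta(s) - theta(0))> = exp(-s / 2P)`` and hence
    the 2D mean squared end-to-end distance

        <D^2> = 4 P L [1 - (2P/L)(1 - e^{-L/2P})].

    Returned vertices are in nm (params are in um).
    """
    rng = np.random.default_rng(params.seed)
    n_seg = max(1, int(round(params.total_length / params.step)))
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    dtheta = rng.normal(0.0, math.sqrt(params.step / params.persistence_length),
                        size=n_seg)
    theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta[:-1])])
    steps = params.step * np.column_stack([np.cos(theta), np.sin(theta)])
    verts_um = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return FibrilTrace(verts_um * 1000.0, fibril_id=fibril_id)


def generate_trace_ensemble(persistence_length: float, n: int,
                            length_range: tuple[float, float],
                            step: float = 0.02, seed: int = 42) -> list[FibrilTrace]:
    """Ensemble of ``n`` traces with contour lengths uniform in ``length_range`` (um)."""
    if n < 2:
        raise ParameterError("need n >= 2 traces (downstream fit needs >= 2 points)")
    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise ParameterError("length_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(lo, hi, size=n)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    traces = []
    for i, (length, s) in enumerate(zip(lengths, child_seeds)):
        params = WLCParams(persistence_length=persistence_length,
                           total_length=float(length), step=step, seed=int(s))
        traces.append(generate_wlc_trace(params, fibril_id=f"sim_{i:03d}"))
    return traces


# ---------------------------------------------------------------------------
# Idealised flat protomer layer
# ---------------------------------------------------------------------------


def _sample_arch_path(n_points: int, spacing: float, gap: float = 9.5) -> np.ndarray:
    """Points at equal arclength ``spacing`` along straight-turn-straight path."""
    total = (n_points - 1) * spacing
    turn = math.pi * gap / 2.0
    arm = (total - turn) / 2.0
    s_values = np.arange(n_points) * spacing
    pts = np.empty((n_points, 2))
    if arm < spacing:  # too short to arch: straight strand
        pts[:, 0] = s_values
        pts[:, 1] = 0.0
        return pts
    for i, s in enumerate(s_values):
        if s <= arm:
            pts[i] = (s, 0.0)
        elif s <= arm + turn:
            phi = (s - arm) / (gap / 2.0)  # 0..pi around the turn
            cx, cy = arm, gap / 2.0
            pts[i] = (cx + (gap / 2.0) * math.sin(phi),
                      cy - (gap / 2.0) * math.cos(phi))
        else:
            pts[i] = (arm - (s - arm - turn), gap)
    return pts


def generate_beta_arch_layer(n_residues: int, spacing: float = 3.8,
                             sequence: str | None = None,
                             chain: str = "A") -> Layer:
    """Idealised flat (z = 0) protomer layer: a beta-arch of C-alpha atoms
    with strand-like consecutive spacing, plus in-plane N and C backbone
    pseudo-atoms. Lies perpendicular to the helix (z) axis."""
    if n_residues < 4:
        raise ParameterError("need >= 4 residues for a layer")
    if sequence is not None and len(sequence) != n_residues:
        raise ParameterError("sequence length must equal n_residues")
    ca = _sample_arch_path(n_residues, spacing)
    rows = []
    for i in range(n_residues):
        prev_pt = ca[i - 1] if i > 0 else ca[i] - (ca[i + 1] - ca[i])
        next_pt = ca[i + 1] if i < n_residues - 1 else ca[i] + (ca[i] - ca[i - 1])
        tangent = next_pt - prev_pt
        tangent = tangent / np.linalg.norm(tangent)
        res_name = ONE_TO_THREE[sequence[i]] if sequence else "ALA"
        n_pos = ca[i] - 1.2 * tangent
        c_pos = ca[i] + 1.2 * tangent
        for name, el, (x, y) in (("N", "N", n_pos), ("CA", "C", ca[i]),
                                 ("C", "C", c_pos)):
            rows.append((chain, i + 1, res_name, name, el, x, y, 0.0))
    atoms = pd.DataFrame(rows, columns=["chain", "res_seq", "res_name", "name",
                                        "element", "x", "y", "z"])
    return AtomicModel(atoms)


# ---------------------------------------------------------------------------
# Cavity phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """A sealed spherical shell of pseudo-atoms enclosing a void.

    ``void_radius`` is the radius of the probe-free interior for a probe of
    radius ``probe`` (default 1.4 A, water): the innermost atom centres sit
    at ``void_radius + vdW + probe``. ``void_radius = 0`` gives a solid
    ball. ``channel_radius`` bores a cylindrical channel along +x, venting
    the void to the exterior.
    """

    void_radius: float
    shell_thickness: float = 6.0
    atom_spacing: float = 1.0
    atom_element: str = "O"
    probe: float = 1.4
    channel_radius: float | None = None

    def __post_init__(self):
        if self.void_radius < 0:
            raise ParameterError("void_radius must be >= 0")
        if self.shell_thickness < 2.0 * vdw_radius(self.atom_element):
            raise ParameterError("shell_thickness must be >= 2 x vdW radius")
        if self.atom_spacing <= 0:
            raise ParameterError("atom_spacing must be > 0")


_ELEMENT_PSEUDO_RESIDUE = {"O": ("SER", "OG"), "C": ("LEU", "CD1"),
                           "N": ("ASN", "ND2"), "S": ("CYS", "SG")}


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def generate_cavity_phantom(spec: PhantomSpec) -> AtomicModel:
    """Build a shell phantom whose interior void has a known analytic volume.

    Raises :class:`ConstructionError` if ``atom_spacing`` is too coarse to
    seal the shell against a 1.4 A probe.
    """
    if spec.atom_spacing > 1.5:
        raise ConstructionError(
            "atom_spacing > 1.5 A cannot guarantee a probe-tight shell")
    rvdw = vdw_radius(spec.atom_element)
    r_inner = (spec.void_radius + rvdw + spec.probe) if spec.void_radius > 0 else 0.0
    dr = spec.atom_spacing * 0.9
    radii = np.arange(r_inner, r_inner + spec.shell_thickness + 1e-9, dr)
    points = []
    for r in radii:
        if r < 1e-9:
            points.append(np.zeros((1, 3)))
            continue
        m = max(6, int(math.ceil(4.0 * math.pi * r * r / spec.atom_spacing ** 2)))
        points.append(_fibonacci_sphere(m) * r)
    xyz = np.vstack(points)
    if spec.channel_radius is not None:
        rho = np.hypot(xyz[:, 1], xyz[:, 2])
        keep = ~((xyz[:, 0] > 0) & (rho < spec.channel_radius))
        xyz = xyz[keep]
    res_name, atom_name = _ELEMENT_PSEUDO_RESIDUE.get(
        spec.atom_element.upper(), ("UNK", spec.atom_element.upper() + "1"))
    atoms = pd.DataFrame({
        "chain": "A",
        "res_seq": np.arange(1, len(xyz) + 1),
        "res_name": res_name,
        "name": atom_name,
        "element": spec.atom_element.upper(),
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
    })
    return AtomicModel(atoms)


# ---------------------------------------------------------------------------
# Ideal-dihedral peptide backbones (for strand-assignment tests)
# ---------------------------------------------------------------------------

_BOND_N_CA, _BOND_CA_C, _BOND_C_N = 1.458, 1.525, 1.329
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Natural-extension (NeRF) placement of atom d from frame (a, b, c)."""
    # +180 maps the placement frame's torsion onto the IUPAC dihedral a-b-c-d
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg + 180.0)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(tor),
                        bond * math.sin(ang) * math.sin(tor)])
    return c + m @ d_local


def build_dihedral_backbone(phi_psi, chain: str = "A",
                            res_name: str = "ALA") -> AtomicModel:
    """Ideal N-CA-C backbone with the given per-residue (phi, psi) in degrees.

    phi of the first residue and psi of the last are irrelevant (no flanking
    peptide bond) but must still be supplied. Omega is fixed trans (180).
    """
    phi_psi = list(phi_psi)
    if len(phi_psi) < 2:
        raise ParameterError("need >= 2 residues")
    coords = {}  # (res_index, atom) -> xyz
    ang = math.radians(180.0 - _ANG_N_CA_C)
    coords[(0, "N")] = np.zeros(3)
    coords[(0, "CA")] = np.array([_BOND_N_CA, 0.0, 0.0])
    coords[(0, "C")] = coords[(0, "CA")] + _BOND_CA_C * np.array(
        [math.cos(ang), math.sin(ang), 0.0])
    for i in range(len(phi_psi) - 1):
        psi_i = phi_psi[i][1]
        phi_next = phi_psi[i + 1][0]
        coords[(i + 1, "N")] = _place_atom(coords[(i, "N")], coords[(i, "CA")],
                                           coords[(i, "C")], _BOND_C_N,
                                           _ANG_CA_C_N, psi_i)
        coords[(i + 1, "CA")] = _place_atom(coords[(i, "CA")], coords[(i, "C")],
                                            coords[(i + 1, "N")], _BOND_N_CA,
                                            _ANG_C_N_CA, 180.0)
        coords[(i + 1, "C")] = _place_atom(coords[(i, "C")], coords[(i + 1, "N")],
                                           coords[(i + 1, "CA")], _BOND_CA_C,
                                           _ANG_N_CA_C, phi_next)
    rows = []
    for i in range(len(phi_psi)):
        for name in ("N", "CA", "C"):
            x, y, z = coords[(i, name)]
            rows.append((chain, i + 1, res_name, name,
                         "N" if name == "N" else "C", x, y, z))
    atoms = pd.DataFrame(rows, columns=["chain", "res_seq", "res_name", "name",
                                        "element", "x", "y", "z"])
    return AtomicModel(atoms)


# ---------------------------------------------------------------------------
# Germline / patient sequence pair
# ---------------------------------------------------------------------------

#: Synthetic reconstructed lambda-light-chain variable-region template.
#: This is NOT an experimentally determined patient or database sequence:
#: it is a packaged placeholder assembled so that every residue identity
#: the analysis relies on (Cys22/Cys89 of the conserved disulfide, the
#: wild-type residues at the ten mutated positions, Gly15 ... Thr105 of
#: the ordered core) is honoured under 1-based mature-chain numbering.
GERMLINE_TEMPLATE_SYNTHETIC = (
    "QSVLTQPPSASGTPGQRVTISCSGSSSNIGSNTVNWYQQLPGTAPKLLIYSNNQRPSGVPDRFSGSKSGTSASLAISGLQSEDEADYYCAAWDDSLNGWVFGGGTKLTVLG"
)

#: The ten germline -> patient substitutions, (from, 1-based position, to).
PATIENT_MUTATIONS: list[tuple[str, int, str]] = [
    ("S", 25, "R"), ("S", 31, "R"), ("T", 33, "L"), ("N", 35, "K"),
    ("L", 40, "F"), ("N", 53, "D"), ("I", 76, "V"), ("D", 94, "A"),
    ("S", 95, "T"), ("G", 98, "A"),
]

#: Ordered fibril core residue range (inclusive, mature numbering).
ORDERED_CORE_RANGE = (15, 105)

_MUT_RE = re.compile(r"^([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3})$")
_THREE_TO_ONE_LOWER = {k.capitalize(): v for k, v in
                       {t: o for o, t in ONE_TO_THREE.items()}.items()}


def parse_mutation(text: str) -> tuple[str, int, str]:
    """Parse 'S25R' or 'Ser25Arg' into (from, position, to)."""
    m = _MUT_RE.match(text.strip())
    if not m:
        raise ParameterError(f"cannot parse mutation {text!r}")
    def to_one(code: str) -> str:
        if len(code) == 1:
            return code.upper()
        one = {t.capitalize(): o for o, t in ONE_TO_THREE.items()}.get(code.capitalize())
        if one is None:
            raise ParameterError(f"unknown residue code {code!r} in {text!r}")
        return one
    return to_one(m.group(1)), int(m.group(2)), to_one(m.group(3))


def apply_mutations(sequence: str, mutations) -> str:
    """Apply (from, 1-based position, to) substitutions to a sequence.

    The stated ``from`` residue must match the sequence — this guards the
    numbering convention. Accepts tuples or strings like 'Ser25Arg'.
    """
    seq = list(sequence)
    for mut in mutations:
        if isinstance(mut, str):
            mut = parse_mutation(mut)
        wt, pos, new = mut
        if not (1 <= pos <= len(seq)):
            raise ParameterError(f"position {pos} outside sequence of length {len(seq)}")
        if seq[pos - 1] != wt.upper():
            raise MutationMismatchError(
                f"expected {wt} at position {pos}, sequence has {seq[pos - 1]}")
        seq[pos - 1] = new.upper()
    return "".join(seq)


def patient_sequence_synthetic() -> str:
    """Synthetic patient-like sequence: template plus the ten substitutions."""
    return apply_mutations(GERMLINE_TEMPLATE_SYNTHETIC, PATIENT_MUTATIONS)
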