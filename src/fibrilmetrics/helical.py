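"""Helical (screw) symmetry of a single-protofilament fibril.

Consecutive protein layers of an amyloid protofilament are related by a
screw operation: a rotation by the helical twist (degrees, signed; negative
= left-handed) about the fibril axis combined with a translation by the
helical rise (A) along it. The axial coordinate convention is z.

pitch = rise * 360 / |twist|;  cross-over distance = pitch / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .exceptions import InputError, ParameterError
from .scales import vdw_radius
from .structure import AtomicModel, Layer, concat_models

#: Guard against accidentally building astronomically large stacks.
MAX_STACK_ATOMS = 2_000_000

_CHAIN_LABELS = [chr(c) for c in range(65, 91)] + [chr(c) for c in range(97, 123)]


@dataclass(frozen=True)
class HelicalSymmetry:
    """Screw operation relating consecutive layers: rise (A) and signed
    twist (degrees; negative = left-handed). twist = 0 is allowed and means
    a pure translation."""

    rise: float
    twist: float

    def __post_init__(self):
        if self.rise <= 0:
            raise ParameterError("rise must be > 0")
        if abs(self.twist) > 360:
            raise ParameterError("|twist| must be <= 360 degrees")

    @property
    def handedness(self) -> str:
        if self.twist < 0:
            return "left"
        if self.twist > 0:
            return "right"
        return "none"


def pitch_and_crossover(sym: HelicalSymmetry) -> tuple[float, float, str]:
    """(pitch A, cross-over A, handedness). Pure translation -> infinite pitch."""
    if sym.twist == 0:
        return math.inf, math.inf, "none"
    pitch = sym.rise * 360.0 / abs(sym.twist)
    return pitch, pitch / 2.0, sym.handedness


def _screw_matrix(sym: HelicalSymmetry, k: int) -> tuple[np.ndarray, np.ndarray]:
    ang = math.radians(sym.twist * k)
    c, s = math.cos(ang), math.sin(ang)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return rot, np.array([0.0, 0.0, sym.rise * k])


def build_stack(layer: Layer, sym: HelicalSymmetry, n_layers: int) -> AtomicModel:
    """Stack ``n_layers`` copies of a layer under the screw operation.

    Layer k is layer 0 rotated by k*twist about z and translated k*rise
    along z. Chains are relabelled A, B, C, ... and annotated with their
    layer index.
    """
    if n_layers < 1:
        raise ParameterError("n_layers must be >= 1")
    if n_layers * len(layer) > MAX_STACK_ATOMS:
        raise ParameterError(
            f"stack would exceed the {MAX_STACK_ATOMS}-atom cap")
    if n_layers > len(_CHAIN_LABELS):
        raise ParameterError(f"at most {len(_CHAIN_LABELS)} layers supported")
    parts, layer_map = [], {}
    for k in range(n_layers):
        rot, t = _screw_matrix(sym, k)
        label = _CHAIN_LABELS[k]
        parts.append(layer.transformed(rot, t).with_chain_label(label))
        layer_map[label] = k
    return concat_models(parts, layer_map)


# ---------------------------------------------------------------------------
# Symmetry estimation from an atomic model
# ---------------------------------------------------------------------------


@dataclass
class SymmetryEstimate:
    """Best-fit screw parameters with superposition residual."""

    symmetry: HelicalSymmetry
    rmsd: float          # residual RMSD of consecutive-layer superpositions, A
    axis: np.ndarray     # unit vector, oriented with positive rise
    axis_point: np.ndarray  # a point on the screw axis


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Rigid transform (R, t) minimising |R P + t - Q|, plus residual RMSD."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


def _matched_coords(model: AtomicModel, chain_a: str, chain_b: str) -> tuple[np.ndarray, np.ndarray]:
    a = model.select_chain(chain_a).atoms.sort_values(["res_seq", "name"])
    b = model.select_chain(chain_b).atoms.sort_values(["res_seq", "name"])
    if len(a) != len(b) or not (a["name"].to_numpy() == b["name"].to_numpy()).all():
        raise InputError(f"chains {chain_a!r} and {chain_b!r} have unmatched atom sets")
    return (a[["x", "y", "z"]].to_numpy(float), b[["x", "y", "z"]].to_numpy(float))


def estimate_symmetry_from_model(model: AtomicModel) -> SymmetryEstimate:
    """Recover (rise, signed twist) from >= 2 stacked chains.

    Each consecutive chain pair is superposed (Kabsch); the rigid transform
    is decomposed into a rotation about, and a translation along, its screw
    axis. The axis is oriented so the rise is positive; the twist sign then
    encodes handedness (negative = left-handed).
    """
    chains = sorted(model.chains, key=lambda c: model.chain_layers()[c])
    if len(chains) < 2:
        raise InputError("need >= 2 chains to estimate helical symmetry")
    rises, twists, axes, points, rmsds = [], [], [], [], []
    for ca, cb in zip(chains[:-1], chains[1:]):
        P, Q = _matched_coords(model, ca, cb)
        R, t, rmsd = _kabsch(P, Q)
        rotvec = Rotation.from_matrix(R).as_rotvec()
        angle = float(np.linalg.norm(rotvec))
        if angle < 1e-12:
            u = t / np.linalg.norm(t)
            twist_deg = 0.0
        else:
            u = rotvec / angle
            if np.dot(t, u) < 0:
                u = -u
            twist_deg = math.degrees(float(np.dot(rotvec, u)))
        rise = float(np.dot(t, u))
        # axis point: solve (I - R) a = t_perp on the plane a . u = 0
        t_perp = t - rise * u
        A = np.vstack([np.eye(3) - R, u[None, :]])
        b = np.concatenate([t_perp, [0.0]])
        a_pt = np.linalg.lstsq(A, b, rcond=None)[0]
        rises.append(rise)
        twists.append(twist_deg)
        axes.append(u)
        points.append(a_pt)
        rmsds.append(rmsd)
    axis = np.mean(axes, axis=0)
    axis /= np.linalg.norm(axis)
    sym = HelicalSymmetry(rise=float(np.mean(rises)), twist=float(np.mean(twists)))
    return SymmetryEstimate(symmetry=sym, rmsd=float(np.mean(rmsds)),
                            axis=axis, axis_point=np.mean(points, axis=0))


def align_to_axis(model: AtomicModel) -> AtomicModel:
    """Rigidly move a stacked model so its screw axis is z through the origin."""
    est = estimate_symmetry_from_model(model)
    u = est.axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(u, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        R = np.eye(3) if np.dot(u, z) > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        R, _ = Rotation.align_vectors(z[None, :], u[None, :])
        R = R.as_matrix()
    return model.transformed(R, -R @ est.axis_point)


# ---------------------------------------------------------------------------
# Geometry measurements on aligned models
# ---------------------------------------------------------------------------


def axial_height_span(model: AtomicModel, chain: str) -> float:
    """Height change of one chain along the fibril axis: max - min C-alpha z (A)."""
    ca = model.ca_atoms(chain)
    if ca.empty:
        raise InputError(f"chain {chain!r} has no C-alpha atoms")
    return float(ca["z"].max() - ca["z"].min())


def measure_width(model: AtomicModel, mode: str = "center") -> float:
    """Maximal extent of the cross-section perpendicular to the axis (A).

    ``mode='center'``: atom-centre extent (maximum projected pairwise
    distance). ``mode='surface'``: adds the vdW radii of the extreme pair,
    approximating the envelope a density map would show.
    """
    if model.n_atoms == 0:
        raise InputError("empty model")
    if mode not in ("center", "surface"):
        raise ParameterError("mode must be 'center' or 'surface'")
    xy = model.coords()[:, :2]
    if len(xy) == 1:
        return 0.0 if mode == "center" else 2.0 * vdw_radius(model.atoms["element"].iloc[0])
    # reduce to the planar convex hull before the O(n^2) pair scan
    pts_idx = np.arange(len(xy))
    if len(xy) > 50:
        from scipy.spatial import ConvexHull, QhullError
        try:
            pts_idx = np.unique(ConvexHull(xy).vertices)
        except QhullError:  # degenerate (collinear) projections
            pass
    sub = xy[pts_idx]
    diff = sub[:, None, :] - sub[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    if mode == "center":
        return float(dist.max())
    radii = model.atoms["element"].map(vdw_radius).to_numpy(float)[pts_idx]
    return float((dist + radii[:, None] + radii[None, :]).max())


# ---------------------------------------------------------------------------
# Inter-layer contacts
# ---------------------------------------------------------------------------

_BASIC_SIDECHAIN_N = {("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
                      ("LYS", "NZ")}
_ACIDIC_SIDECHAIN_O = {("ASP", "OD1"), ("ASP", "OD2"),
                       ("GLU", "OE1"), ("GLU", "OE2")}


@dataclass
class ContactMap:
    """Residue-residue contacts annotated by layer offset.

    ``entries`` columns: res_a, res_a_name, res_b, res_b_name, offset,
    min_distance, salt_bridge. Offsets are canonicalised to >= 0 (entry
    stored with the lower layer first); for offset 0, res_a <= res_b.
    """

    entries: pd.DataFrame
    cutoff: float

    def at_offset(self, offset: int) -> pd.DataFrame:
        return self.entries[self.entries["offset"] == offset]

    def between(self, res_a: int, res_b: int, offset: int) -> pd.DataFrame:
        e = self.entries
        return e[(e["res_a"] == res_a) & (e["res_b"] == res_b)
                 & (e["offset"] == offset)]

    def salt_bridges(self) -> pd.DataFrame:
        return self.entries[self.entries["salt_bridge"]]


def interlayer_contacts(model: AtomicModel, cutoff: float = 4.5,
                        salt_bridge_cutoff: float = 4.0) -> ContactMap:
    """All residue pairs with minimum heavy-atom distance <= cutoff,
    annotated by layer offset, with a salt-bridge flag when oppositely
    charged side-chain N/O atoms come within ``salt_bridge_cutoff``."""
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    layers = model.chain_layers()
    if len(set(layers.values())) < 2:
        raise InputError("need >= 2 layers for inter-layer contacts")
    heavy = model.heavy().atoms
    xyz = heavy[["x", "y", "z"]].to_numpy(float)
    layer = heavy["chain"].map(layers).to_numpy(int)
    res = heavy["res_seq"].to_numpy(int)
    res_name = heavy["res_name"].to_numpy(object)
    name = heavy["name"].to_numpy(object)
    is_basic = np.array([(rn, nm) in _BASIC_SIDECHAIN_N
                         for rn, nm in zip(res_name, name)])
    is_acidic = np.array([(rn, nm) in _ACIDIC_SIDECHAIN_O
                          for rn, nm in zip(res_name, name)])
    pairs = cKDTree(xyz).query_pairs(cutoff, output_type="ndarray")
    records: dict[tuple, list] = {}
    for i, j in pairs:
        if layer[i] == layer[j] and res[i] == res[j]:
            continue  # intra-residue
        # canonical order: lower layer first; within a layer, lower residue
        if (layer[i], res[i]) > (layer[j], res[j]):
            i, j = j, i
        key = (res[i], res[j], layer[j] - layer[i])
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        sb = bool(d <= salt_bridge_cutoff
                  and ((is_basic[i] and is_acidic[j])
                       or (is_acidic[i] and is_basic[j])))
        rec = records.get(key)
        if rec is None:
            records[key] = [res_name[i], res_name[j], d, sb]
        else:
            rec[2] = min(rec[2], d)
            rec[3] = rec[3] or sb
    rows = [(ra, na, rb, nb, off, d, sb)
            for (ra, rb, off), (na, nb, d, sb) in sorted(records.items())]
    entries = pd.DataFrame(rows, columns=["res_a", "res_a_name", "res_b",
                                          "res_b_name", "offset",
                                          "min_distance", "salt_bridge"])
    return ContactMap(entries=entries, cutoff=cutoff)


def has_perpendicular_c2(model: AtomicModel, tolerance_rmsd: float = 1.0) -> bool:
    """Check for a 2-fold axis perpendicular to the helix axis (absent in a
    polar, single-protofilament fibril): flip the model by 180 degrees about
    x and test whether it superposes onto itself."""
    xyz = model.coords()
    flipped = xyz @ np.diag([1.0, -1.0, -1.0])
    tree = cKDTree(xyz)
    d, _ = tree.query(flipped)
    return bool(np.sqrt(np.mean(d ** 2)) <= tolerance_rmsd)
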