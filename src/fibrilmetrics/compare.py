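"""Native-vs-fibril conformational comparison.

Quantifies how a natively folded immunoglobulin V_L domain differs from its
fibril conformation: beta-strand positions along the sequence (dihedral
heuristic), residue-level strand-registry overlap, the relative orientation
of the two disulfide-anchored segments (the rotational switch), and the
disulfide geometry itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError, ParameterError
from .structure import AtomicModel

#: Dihedral box counted as beta/extended: phi in [-180, -45] and
#: psi in [45, 180] or [-180, -170] (the region wraps through 180).
BETA_PHI = (-180.0, -45.0)
BETA_PSI = ((45.0, 180.0), (-180.0, -170.0))

#: Peptide-bond C-N distance above which a chain break is assumed (A).
CHAIN_BREAK_CN = 2.0


@dataclass(frozen=True)
class StrandSegment:
    """An extended (beta) segment, inclusive residue numbers."""

    start: int
    end: int
    source: str = ""

    def __post_init__(self):
        if self.end < self.start:
            raise ParameterError("segment end before start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> set[int]:
        return set(range(self.start, self.end + 1))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(model: AtomicModel, chain: str | None = None) -> pd.DataFrame:
    """Phi/psi per residue (NaN where a flanking residue or atom is missing,
    or across a chain break). Residues lacking backbone atoms are skipped."""
    df = model.atoms if chain is None else model.select_chain(chain).atoms
    backbone: dict[int, dict[str, np.ndarray]] = {}
    for res_seq, grp in df.groupby("res_seq"):
        atoms = {name: np.array([x, y, z])
                 for name, x, y, z in zip(grp["name"], grp["x"], grp["y"], grp["z"])
                 if name in ("N", "CA", "C")}
        if len(atoms) == 3:
            backbone[int(res_seq)] = atoms
    rows = []
    for r in sorted(backbone):
        phi = psi = float("nan")
        cur = backbone[r]
        prev, nxt = backbone.get(r - 1), backbone.get(r + 1)
        if prev is not None and np.linalg.norm(cur["N"] - prev["C"]) <= CHAIN_BREAK_CN:
            phi = dihedral_angle(prev["C"], cur["N"], cur["CA"], cur["C"])
        if nxt is not None and np.linalg.norm(nxt["N"] - cur["C"]) <= CHAIN_BREAK_CN:
            psi = dihedral_angle(cur["N"], cur["CA"], cur["C"], nxt["N"])
        rows.append((r, phi, psi))
    return pd.DataFrame(rows, columns=["res_seq", "phi", "psi"])


def _is_beta(phi: float, psi: float) -> bool:
    if math.isnan(phi) or math.isnan(psi):
        return False
    if not BETA_PHI[0] <= phi <= BETA_PHI[1]:
        return False
    return any(lo <= psi <= hi for lo, hi in BETA_PSI)


def assign_extended_strands(model: AtomicModel, chain: str | None = None,
                            source: str = "") -> list[StrandSegment]:
    """Maximal runs (length >= 2) of residues whose backbone dihedrals fall
    in the extended/beta region."""
    dih = backbone_dihedrals(model, chain)
    segments: list[StrandSegment] = []
    run: list[int] = []
    beta_residues = {int(r.res_seq) for r in dih.itertuples()
                     if _is_beta(r.phi, r.psi)}
    for r in [*sorted(beta_residues), None]:
        if run and (r is None or r != run[-1] + 1):
            if len(run) >= 2:
                segments.append(StrandSegment(run[0], run[-1], source))
            run = []
        if r is not None:
            run.append(r)
    return segments


@dataclass
class OverlapReport:
    """Residue-level strand-coverage agreement between two segment sets."""

    per_residue: pd.DataFrame  # columns: res_seq, in_a, in_b
    jaccard: float


def strand_registry_overlap(segments_a, segments_b) -> OverlapReport:
    """Intersection/union of strand coverage (same numbering scheme)."""
    set_a: set[int] = set().union(*[s.residues() for s in segments_a], set())
    set_b: set[int] = set().union(*[s.residues() for s in segments_b], set())
    union = sorted(set_a | set_b)
    per_res = pd.DataFrame({
        "res_seq": union,
        "in_a": [r in set_a for r in union],
        "in_b": [r in set_b for r in union],
    })
    jaccard = (len(set_a & set_b) / len(union)) if union else float("nan")
    return OverlapReport(per_residue=per_res, jaccard=jaccard)


# ---------------------------------------------------------------------------
# Segment orientation and the rotational switch
# ---------------------------------------------------------------------------


def _segment_direction(model: AtomicModel, res_range: tuple[int, int],
                       chain: str | None, method: str) -> np.ndarray:
    lo, hi = res_range
    if hi - lo + 1 < 3:
        raise ParameterError("segment must span >= 3 residues")
    ca = model.ca_atoms(chain)
    ca = ca[(ca["res_seq"] >= lo) & (ca["res_seq"] <= hi)]
    missing = sorted(set(range(lo, hi + 1)) - set(ca["res_seq"]))
    if missing:
        raise InputError(f"residues {missing} unresolved in range {lo}-{hi}")
    xyz = ca[["x", "y", "z"]].to_numpy(float)
    endpoint = xyz[-1] - xyz[0]
    if method == "endpoints":
        direction = endpoint
    elif method == "pca":
        centered = xyz - xyz.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
        if np.dot(direction, endpoint) < 0:  # orient N -> C
            direction = -direction
    else:
        raise ParameterError("method must be 'pca' or 'endpoints'")
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise InputError("segment endpoints coincide; direction undefined")
    return direction / norm


def relative_orientation(model: AtomicModel, range_a: tuple[int, int],
                         range_b: tuple[int, int], chain: str | None = None,
                         method: str = "pca") -> float:
    """Angle (degrees, [0, 180]) between the N-to-C directions of two
    C-alpha segments. Direction = principal component of the segment's
    C-alpha coordinates oriented N->C ('pca', default) or the first-to-last
    vector ('endpoints')."""
    va = _segment_direction(model, range_a, chain, method)
    vb = _segment_direction(model, range_b, chain, method)
    cos = float(np.clip(np.dot(va, vb), -1.0, 1.0))
    return math.degrees(math.acos(cos))


@dataclass
class SwitchReport:
    """Orientation of the two disulfide-anchored segments in both states."""

    angle_native: float
    angle_fibril: float
    range_a: tuple[int, int]
    range_b: tuple[int, int]

    @staticmethod
    def _classify(angle: float) -> str:
        return "parallel" if angle < 90.0 else "antiparallel"

    @property
    def classification_native(self) -> str:
        return self._classify(self.angle_native)

    @property
    def classification_fibril(self) -> str:
        return self._classify(self.angle_fibril)

    @property
    def switch_detected(self) -> bool:
        return self.classification_native != self.classification_fibril

    def to_dict(self) -> dict:
        return {
            "angle_native_deg": self.angle_native,
            "angle_fibril_deg": self.angle_fibril,
            "classification_native": self.classification_native,
            "classification_fibril": self.classification_fibril,
            "switch_detected": self.switch_detected,
            "segments": [list(self.range_a), list(self.range_b)],
        }


def switch_report(native: AtomicModel, fibril: AtomicModel,
                  range_a: tuple[int, int] = (16, 23),
                  range_b: tuple[int, int] = (86, 93),
                  native_chain: str | None = None,
                  fibril_chain: str | None = None) -> SwitchReport:
    """Quantify the rotational switch: relative orientation of the two
    disulfide-flanking segments in the native and the fibril state.
    Parallel (< 90 deg) vs antiparallel (> 90 deg); the switch is detected
    when the classifications differ."""
    ang_nat = relative_orientation(native, range_a, range_b, chain=native_chain)
    ang_fib = relative_orientation(fibril, range_a, range_b, chain=fibril_chain)
    return SwitchReport(angle_native=ang_nat, angle_fibril=ang_fib,
                        range_a=range_a, range_b=range_b)


#: Accepted S-S bond window (A) around the 2.05 A canonical disulfide.
DISULFIDE_WINDOW = (1.8, 2.5)


def disulfide_geometry(model: AtomicModel, res_a: int = 22, res_b: int = 89,
                       chain: str | None = None) -> tuple[float, bool]:
    """(S-gamma to S-gamma distance in A, bonded?) for a cysteine pair.

    Bonded iff the distance falls in the documented window [1.8, 2.5] A.
    """
    def sg(res_seq: int) -> np.ndarray:
        res = model.residue(res_seq, chain=chain)
        if res["res_name"].iloc[0] != "CYS":
            raise InputError(f"residue {res_seq} is {res['res_name'].iloc[0]}, "
                             "not CYS")
        atom = res[res["name"] == "SG"]
        if atom.empty:
            raise InputError(f"residue {res_seq} lacks an SG atom")
        return atom[["x", "y", "z"]].to_numpy(float)[0]

    d = float(np.linalg.norm(sg(res_a) - sg(res_b)))
    lo, hi = DISULFIDE_WINDOW
    return d, lo <= d <= hi
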