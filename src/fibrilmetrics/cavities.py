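"""Sealed interior voids of an atomic model by occupancy-grid flood fill.

A regular grid is laid over the padded bounding box; voxels within
(vdW radius + probe radius) of any atom are occupied. Free voxels
6-connected to the grid boundary are exterior solvent; the remaining free
connected components are interior cavities. Volumes are voxel counts times
the voxel volume, so they converge to the geometric void volume as the
spacing shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .exceptions import InputError, ParameterError
from .scales import BACKBONE_ATOMS, vdw_radius
from .structure import AtomicModel

#: Elements whose side-chain atoms count as polar when classifying linings.
POLAR_ELEMENTS = {"N", "O"}


@dataclass
class Cavity:
    """One connected interior void."""

    voxel_indices: np.ndarray      # (n, 3) int grid indices
    spacing: float                 # A
    origin: np.ndarray             # grid origin (A)
    volume: float                  # A^3 (= n voxels * spacing^3)
    label: str = ""
    lining_residues: pd.DataFrame | None = None  # chain, res_seq, res_name
    polar_fraction: float | None = None
    polarity_class: str | None = None            # hydrophilic | hydrophobic

    def voxel_centers(self) -> np.ndarray:
        return self.origin + (self.voxel_indices + 0.5) * self.spacing

    @property
    def centroid(self) -> np.ndarray:
        return self.voxel_centers().mean(axis=0)


def _occupancy_grid(coords: np.ndarray, radii: np.ndarray, spacing: float,
                    pad: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean occupied grid and its origin."""
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    occ = np.zeros(shape, dtype=bool)
    # mark a sphere of voxels per atom; atoms grouped by radius to reuse masks
    for r in np.unique(radii):
        nr = int(np.ceil(r / spacing)) + 1
        offs = np.arange(-nr, nr + 1)
        ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
        centers = (np.stack([ox, oy, oz], axis=-1) .reshape(-1, 3))
        # voxel-center distance test against the atom center placed on its
        # fractional grid position would need per-atom masks; instead test
        # against the worst-case sub-voxel offset and refine per atom below
        for xyz in coords[radii == r]:
            base = np.floor((xyz - lo) / spacing - 0.5).astype(int)
            vox = base + centers
            cent = lo + (vox + 0.5) * spacing
            inside = np.linalg.norm(cent - xyz, axis=1) <= r
            vox = vox[inside]
            ok = np.all((vox >= 0) & (vox < shape), axis=1)
            vox = vox[ok]
            occ[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return occ, lo


def find_cavities(model: AtomicModel, spacing: float = 0.5, probe: float = 1.4,
                  min_volume: float = 20.0) -> list[Cavity]:
    """Interior cavities of a model, sorted by volume (descending).

    Voxels within (vdW + probe) of any heavy atom are occupied; free voxels
    6-connected to the boundary are exterior; the remaining free components
    with volume >= ``min_volume`` (A^3) are reported, labelled 'A', 'B', ...
    """
    if not 0.2 <= spacing <= 1.5:
        raise ParameterError("spacing must be in [0.2, 1.5] A")
    if probe < 0:
        raise ParameterError("probe must be >= 0")
    heavy = model.heavy()
    if heavy.n_atoms == 0:
        raise InputError("empty model")
    coords = heavy.coords()
    radii = heavy.atoms["element"].map(vdw_radius).to_numpy(float) + probe
    pad = 2.0 * radii.max()
    occ, origin = _occupancy_grid(coords, radii, spacing, pad)
    free = ~occ
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n_labels = ndimage.label(free, structure=structure)
    if n_labels == 0:
        return []
    boundary = np.unique(np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
    exterior = set(boundary.tolist()) | {0}
    cavities = []
    counts = np.bincount(labels.ravel())
    for lab in range(1, n_labels + 1):
        if lab in exterior:
            continue
        volume = counts[lab] * spacing ** 3
        if volume < min_volume:
            continue
        idx = np.argwhere(labels == lab)
        cavities.append(Cavity(voxel_indices=idx, spacing=spacing,
                               origin=origin, volume=float(volume)))
    cavities.sort(key=lambda c: -c.volume)
    for i, cav in enumerate(cavities):
        cav.label = chr(ord("A") + i) if i < 26 else f"cav{i}"
    return cavities


def cavity_polarity_report(model: AtomicModel, cavity: Cavity,
                           lining_cutoff: float = 4.5) -> Cavity:
    """Annotate a cavity with its lining residues and polarity class.

    Lining residues have any heavy atom within ``lining_cutoff`` of a cavity
    voxel centre. The polar-lining fraction is the share of polar (N/O)
    atoms among lining side-chain atoms; >= 0.5 classifies hydrophilic.
    """
    heavy = model.heavy().atoms
    xyz = heavy[["x", "y", "z"]].to_numpy(float)
    tree = cKDTree(cavity.voxel_centers())
    d, _ = tree.query(xyz, distance_upper_bound=lining_cutoff)
    lining_mask = np.isfinite(d)
    lining = heavy[lining_mask]
    residues = (lining[["chain", "res_seq", "res_name"]]
                .drop_duplicates().sort_values(["chain", "res_seq"])
                .reset_index(drop=True))
    side = lining[~lining["name"].isin(BACKBONE_ATOMS)]
    if len(side) == 0:
        frac = float("nan")
        klass = "unknown"
    else:
        polar = side["element"].str.upper().isin(POLAR_ELEMENTS).sum()
        frac = float(polar / len(side))
        klass = "hydrophilic" if frac >= 0.5 else "hydrophobic"
    return replace(cavity, lining_residues=residues, polar_fraction=frac,
                   polarity_class=klass)


def cavities_to_pseudo_atoms(cavities: list[Cavity]) -> AtomicModel:
    """Cavity voxels as pseudo-atoms (one chain per cavity) for visualisation."""
    rows = []
    for i, cav in enumerate(cavities):
        centers = cav.voxel_centers()
        chain = cav.label or chr(ord("A") + i)
        for j, (x, y, z) in enumerate(centers):
            rows.append((chain, j + 1, "CAV", "DU", "C", x, y, z))
    if not rows:
        raise InputError("no cavities to export")
    atoms = pd.DataFrame(rows, columns=["chain", "res_seq", "res_name", "name",
                                        "element", "x", "y", "z"])
    return AtomicModel(atoms)
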