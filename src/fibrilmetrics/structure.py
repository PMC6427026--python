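"""Lightweight atomic-model container shared by all structural modules.

An :class:`AtomicModel` wraps a pandas DataFrame of labelled heavy-atom
(and optionally hydrogen) coordinates. The axial coordinate convention is
that the fibril/helix axis is the z axis; models imported from deposited
coordinates can be re-aligned with :func:`fibrilmetrics.helical.align_to_axis`.

Residue numbers are 1-based mature-chain numbering throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError

#: Required columns of the atom table.
ATOM_COLUMNS = ["chain", "res_seq", "res_name", "name", "element", "x", "y", "z"]


@dataclass
class AtomicModel:
    """Labelled 3D atom coordinates of one or many fibril layers.

    Parameters
    ----------
    atoms
        DataFrame with columns ``chain, res_seq, res_name, name, element,
        x, y, z`` (coordinates in Angstrom).
    layer_of_chain
        Optional mapping from chain label to integer layer index along the
        fibril axis. When absent, chain order of appearance is used.
    """

    atoms: pd.DataFrame
    layer_of_chain: dict[str, int] | None = field(default=None)

    def __post_init__(self):
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise InputError(f"atom table lacks columns {missing}")
        self.atoms = self.atoms.reset_index(drop=True)

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        """Chain labels in order of first appearance."""
        return list(dict.fromkeys(self.atoms["chain"]))

    def chain_layers(self) -> dict[str, int]:
        """Layer index per chain (explicit mapping or appearance order)."""
        if self.layer_of_chain is not None:
            return dict(self.layer_of_chain)
        return {c: i for i, c in enumerate(self.chains)}

    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    def heavy(self) -> "AtomicModel":
        """Model restricted to non-hydrogen atoms."""
        mask = self.atoms["element"].str.upper() != "H"
        return AtomicModel(self.atoms[mask], self.layer_of_chain)

    def select_chain(self, chain: str) -> "AtomicModel":
        sub = self.atoms[self.atoms["chain"] == chain]
        if sub.empty:
            raise InputError(f"chain {chain!r} not present (have {self.chains})")
        return AtomicModel(sub, None)

    def ca_atoms(self, chain: str | None = None) -> pd.DataFrame:
        """C-alpha rows, ordered by residue number."""
        df = self.atoms if chain is None else self.select_chain(chain).atoms
        ca = df[df["name"] == "CA"].sort_values("res_seq")
        return ca.reset_index(drop=True)

    def residue(self, res_seq: int, chain: str | None = None) -> pd.DataFrame:
        df = self.atoms if chain is None else self.select_chain(chain).atoms
        sub = df[df["res_seq"] == res_seq]
        if sub.empty:
            where = f" in chain {chain!r}" if chain else ""
            raise InputError(f"residue {res_seq} not present{where}")
        return sub

    # -- construction / transformation ------------------------------------

    @classmethod
    def from_arrays(cls, coords: np.ndarray, *, chain: str = "A",
                    res_seq=None, res_name: str = "ALA", name: str = "CA",
                    element: str = "C") -> "AtomicModel":
        """Build a model from an (N, 3) coordinate array, one atom per residue."""
        coords = np.asarray(coords, float)
        n = len(coords)
        if res_seq is None:
            res_seq = np.arange(1, n + 1)
        return cls(pd.DataFrame({
            "chain": chain, "res_seq": np.asarray(res_seq),
            "res_name": res_name, "name": name, "element": element,
            "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        }))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        """Return a rigidly transformed copy (x -> R x + t)."""
        xyz = self.coords() @ np.asarray(rotation, float).T + np.asarray(translation, float)
        atoms = self.atoms.copy()
        atoms[["x", "y", "z"]] = xyz
        return AtomicModel(atoms, self.layer_of_chain)

    def with_chain_label(self, chain: str) -> "AtomicModel":
        atoms = self.atoms.copy()
        atoms["chain"] = chain
        return AtomicModel(atoms, None)

    def copy(self) -> "AtomicModel":
        return AtomicModel(self.atoms.copy(),
                           None if self.layer_of_chain is None else dict(self.layer_of_chain))


def concat_models(parts: list[AtomicModel],
                  layer_of_chain: dict[str, int] | None = None) -> AtomicModel:
    """Concatenate models (chain labels must already be distinct)."""
    atoms = pd.concat([p.atoms for p in parts], ignore_index=True)
    return AtomicModel(atoms, layer_of_chain)


#: A single fibril layer is just a one-chain AtomicModel.
Layer = AtomicModel
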