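"""Shared builders for test structures."""

from __future__ import annotations

import numpy as np

from msmdock import ProteinStructure


def make_structure(atoms, hetero=None, model_id=1) -> ProteinStructure:
    """Build a structure from (res_id, atom_name, element, (x, y, z)) rows."""
    n = len(atoms)
    return ProteinStructure(
        serial=np.arange(1, n + 1),
        atom_name=np.array([a[1] for a in atoms]),
        element=np.array([a[2] for a in atoms]),
        res_id=np.array([a[0] for a in atoms], dtype=int),
        res_name=np.full(n, "ALA"),
        chain_id=np.full(n, "A"),
        coord=np.array([a[3] for a in atoms], dtype=float),
        hetero=np.zeros(n, dtype=bool) if hetero is None else np.asarray(hetero, bool),
        model_id=model_id,
    )


def ca_cloud(coords, model_id=1) -> ProteinStructure:
    """One CA pseudo-atom per residue at the given coordinates."""
    return make_structure(
        [(i + 1, "CA", "C", xyz) for i, xyz in enumerate(np.asarray(coords, float))],
        model_id=model_id,
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
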