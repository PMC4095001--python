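"""Intermolecular residue-residue contacts of single frames.

Two residues, one per binding partner, are in contact when at least one pair
of heavy atoms (one atom from each residue) lies at a Euclidean distance
strictly shorter than the cutoff — 5 A by default, the CAPRI convention.
Neighbor search uses a k-d tree but is, by construction and by test, exactly
equivalent to the exhaustive all-pairs scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptyPartnerError, MDconsError
from .structure_io import Frame, ResidueKey, Trajectory

DEFAULT_CUTOFF = 5.0

Pair = tuple[ResidueKey, ResidueKey]


@dataclass
class ContactSet:
    """The intermolecular contacts of one frame.

    ``pairs`` maps each (partner-A residue, partner-B residue) contact to the
    minimum heavy-atom distance that produced it (A).
    """

    frame_index: int
    pairs: dict[Pair, float] = field(default_factory=dict)

    @property
    def nc(self) -> int:
        """Number of intermolecular contacts in this frame (nc_i)."""
        return len(self.pairs)

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.pairs

    def __iter__(self):
        return iter(sorted(self.pairs))


def frame_contacts(frame: Frame, cutoff: float = DEFAULT_CUTOFF) -> ContactSet:
    """Contacts of one frame under the heavy-atom distance criterion.

    A pair enters the set iff its minimum heavy-atom distance is strictly
    below ``cutoff``; ties at exactly the cutoff are non-contacts.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    frame.validate()
    coords_a, owners_a, _ = frame.heavy_atoms("A")
    coords_b, owners_b, _ = frame.heavy_atoms("B")
    if len(coords_a) == 0 or len(coords_b) == 0:
        raise EmptyPartnerError(
            f"frame {frame.index}: a partner has no heavy atoms"
        )
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    sparse = tree_a.sparse_distance_matrix(tree_b, max_distance=cutoff, output_type="coo_matrix")
    best: dict[Pair, float] = {}
    for ia, ib, dist in zip(sparse.row, sparse.col, sparse.data):
        if dist >= cutoff:  # sparse matrix is inclusive of the cutoff
            continue
        pair = (owners_a[ia], owners_b[ib])
        if dist < best.get(pair, np.inf):
            best[pair] = float(dist)
    return ContactSet(frame_index=frame.index, pairs=best)


def brute_force_contacts(frame: Frame, cutoff: float = DEFAULT_CUTOFF) -> ContactSet:
    """Reference O(n^2) all-pairs scan; the oracle the k-d tree path must match."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    frame.validate()
    coords_a, owners_a, _ = frame.heavy_atoms("A")
    coords_b, owners_b, _ = frame.heavy_atoms("B")
    if len(coords_a) == 0 or len(coords_b) == 0:
        raise EmptyPartnerError(f"frame {frame.index}: a partner has no heavy atoms")
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    dists = np.sqrt((diff * diff).sum(axis=-1))
    best: dict[Pair, float] = {}
    for ia, ib in zip(*np.nonzero(dists < cutoff)):
        pair = (owners_a[ia], owners_b[ib])
        d = float(dists[ia, ib])
        if d < best.get(pair, np.inf):
            best[pair] = d
    return ContactSet(frame_index=frame.index, pairs=best)


def trajectory_contacts(
    traj: Trajectory, cutoff: float = DEFAULT_CUTOFF
) -> list[ContactSet]:
    """Per-frame contact sets, in frame order."""
    traj.validate()
    out = []
    for frame in traj:
        try:
            out.append(frame_contacts(frame, cutoff))
        except MDconsError as exc:
            raise type(exc)(f"frame {frame.index}: {exc}") from exc
    return out


def contacts_table(contact_sets: Iterable[ContactSet] | ContactSet) -> pd.DataFrame:
    """Flatten contact sets into the per-frame contact table.

    Columns: frame, chain_A, resnum_A, resname_A, chain_B, resnum_B,
    resname_B, min_distance_A.
    """
    if isinstance(contact_sets, ContactSet):
        contact_sets = [contact_sets]
    rows = []
    for cs in contact_sets:
        for (ka, kb) in cs:
            rows.append(
                {
                    "frame": cs.frame_index,
                    "chain_A": ka.chain_id,
                    "resnum_A": f"{ka.res_seq}{ka.i_code}",
                    "resname_A": ka.res_name,
                    "chain_B": kb.chain_id,
                    "resnum_B": f"{kb.res_seq}{kb.i_code}",
                    "resname_B": kb.res_name,
                    "min_distance_A": round(cs.pairs[(ka, kb)], 3),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "frame", "chain_A", "resnum_A", "resname_A",
            "chain_B", "resnum_B", "resname_B", "min_distance_A",
        ],
    )


def write_contacts_tsv(
    contact_sets: Iterable[ContactSet] | ContactSet, path: str | Path
) -> Path:
    path = Path(path)
    contacts_table(contact_sets).to_csv(path, sep="\t", index=False)
    return path
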