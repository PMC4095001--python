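"""Synthetic two-partner complexes with controlled contact persistence.

The generator lays two chains of pseudo-residues on parallel lines 8 A (or
more) apart, so that by default no intermolecular contact exists under the
5 A criterion.  Designated "contact slots" — pairs of one partner-A and one
partner-B residue — are brought to 4.5 A, inside the cutoff.  A trajectory
toggles each slot independently per frame with its own persistence
probability p, emulating an interfacial contact that is present in a
fraction p of MD snapshots.  All randomness flows from one seeded generator
and the seed is recorded in a REMARK of the written PDB, so a fixture is
reproducible from its file alone.

This is a geometric null model: residues are single heavy atoms (optionally
three), slots toggle independently, and there is no excluded volume or
correlated motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure_io import Atom, Frame, ResidueKey, Trajectory, write_multimodel_pdb

CONTACT_SEPARATION = 4.5  # A, inside the 5 A criterion
BREAK_SEPARATION = 9.0    # A, safely outside
BASELINE_SEPARATION = 8.0  # A, non-slot residues never in contact


@dataclass(frozen=True)
class ContactSlot:
    """One toggleable contact: 0-based residue indices and persistence p."""

    index_a: int
    index_b: int
    p: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"persistence probability {self.p} outside [0, 1]")


@dataclass
class PersistenceSpec:
    """Full description of a synthetic trajectory."""

    n_res_a: int = 10
    n_res_b: int = 10
    slots: list[ContactSlot] = field(default_factory=list)
    n_frames: int = 10
    seed: int = 0
    spacing: float = 8.0
    multi_atom: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        for slot in self.slots:
            if not (0 <= slot.index_a < self.n_res_a and 0 <= slot.index_b < self.n_res_b):
                raise ValueError(f"slot {slot} references a residue outside the chains")
        if len({s.index_b for s in self.slots}) != len(self.slots):
            raise ValueError("each partner-B residue may serve at most one slot")


# alternate ALA/SER so the polarity classifier is exercisable synthetically
_RES_NAMES = ("ALA", "SER")


def _residue_atoms(x: float, y: float, serial: int, multi_atom: bool) -> list[Atom]:
    if not multi_atom:
        return [Atom(serial, "CA", "C", np.array([x, y, 0.0]), True)]
    return [
        Atom(serial, "N", "N", np.array([x, y, -0.5]), True),
        Atom(serial + 1, "CA", "C", np.array([x, y, 0.0]), True),
        Atom(serial + 2, "C", "C", np.array([x, y, 0.5]), True),
    ]


def _build_frame(
    index: int,
    n_res_a: int,
    n_res_b: int,
    spacing: float,
    b_offsets: dict[int, tuple[float, float]],
    multi_atom: bool,
) -> Frame:
    residues: dict[ResidueKey, list[Atom]] = {}
    partner_of: dict[ResidueKey, str] = {}
    serial = 1
    for i in range(n_res_a):
        key = ResidueKey("A", i + 1, "", _RES_NAMES[i % 2])
        residues[key] = _residue_atoms(i * spacing, 0.0, serial, multi_atom)
        partner_of[key] = "A"
        serial += len(residues[key])
    for j in range(n_res_b):
        x, y = b_offsets.get(j, (j * spacing, BASELINE_SEPARATION))
        key = ResidueKey("B", j + 1, "", _RES_NAMES[j % 2])
        residues[key] = _residue_atoms(x, y, serial, multi_atom)
        partner_of[key] = "B"
        serial += len(residues[key])
    return Frame(index=index, residues=residues, partner_of=partner_of)


def generate_toy_complex(
    n_res_a: int,
    n_res_b: int,
    spacing: float = 8.0,
    slots: Sequence[tuple[int, int]] = (),
    multi_atom: bool = False,
) -> Frame:
    """Single-frame toy complex with the designated slot pairs in contact.

    Slot pairs sit at 4.5 A; every other intermolecular residue pair is at
    least 8 A apart.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if n_res_a < 1 or n_res_b < 1:
        raise ValueError("each chain needs at least one residue")
    spec_slots = [ContactSlot(a, b, 1.0) for a, b in slots]
    PersistenceSpec(n_res_a, n_res_b, spec_slots, n_frames=1, spacing=spacing)  # validates
    offsets = {b: (a * spacing, CONTACT_SEPARATION) for a, b in slots}
    return _build_frame(0, n_res_a, n_res_b, spacing, offsets, multi_atom)


def generate_trajectory(spec: PersistenceSpec) -> Trajectory:
    """Multi-frame toy trajectory with seeded per-slot contact persistence."""
    if spec.spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(spec.seed)
    frames = []
    for t in range(spec.n_frames):
        offsets: dict[int, tuple[float, float]] = {}
        for slot in spec.slots:
            on = rng.random() < slot.p
            y = CONTACT_SEPARATION if on else BREAK_SEPARATION
            offsets[slot.index_b] = (slot.index_a * spec.spacing, y)
        frames.append(
            _build_frame(t, spec.n_res_a, spec.n_res_b, spec.spacing, offsets, spec.multi_atom)
        )
    remarks = [
        f"SYNTHETIC FIXTURE seed={spec.seed} n_frames={spec.n_frames}",
        "slots=" + ";".join(f"{s.index_a},{s.index_b},{s.p}" for s in spec.slots),
    ]
    return Trajectory(frames=frames, remarks=remarks)


def write_trajectory_fixture(spec: PersistenceSpec, path: str | Path) -> Path:
    """Generate and write a persistence fixture as a multi-model PDB."""
    return write_multimodel_pdb(generate_trajectory(spec), path)
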