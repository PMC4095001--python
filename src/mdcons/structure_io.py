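"""Read and write snapshot ensembles of a two-partner complex.

A trajectory here is an ordered list of frames, each frame being the set of
residues of the complex with their atoms, every residue assigned to binding
partner ``A`` or ``B``.  Input is the plain PDB format: either one multi-model
file (one MODEL block per snapshot) or an ordered set of single-model snapshot
files.  Parsing is delegated to Biopython's ``Bio.PDB``; this module only
enforces the filtering rules (partner chains, water/heteroatom handling,
alternate-location resolution) and builds the stable residue registry that the
downstream contact statistics rely on.

Conventions
-----------
* Coordinates and all cutoffs are in Angstrom; residue numbering is taken
  verbatim from the PDB file (author numbering, insertion codes kept).
* Hydrogens (and deuteriums) are retained but flagged ``is_heavy=False``;
  contact detection and surface areas use heavy atoms only.
* Waters are always dropped.  HETATM records are dropped unless
  ``include_het`` is set, with the exception of selenomethionine (MSE), which
  is part of the polymer and is always kept.
* Alternate locations are resolved to the highest-occupancy conformer
  (ties: first encountered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import (
    ChainSelectionError,
    EmptyPartnerError,
    MissingInputError,
    NoModelsError,
)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3", "SOL"}
_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue, stable across frames.

    ``(chain_id, res_seq, i_code)`` is the identity used for equality and
    ordering; ``res_name`` is carried along for reporting but does not take
    part in comparisons, so a residue keeps a single registry slot even if a
    naming quirk changes across snapshots.
    """

    chain_id: str
    res_seq: int
    i_code: str = ""
    res_name: str = field(default="UNK", compare=False)

    def __str__(self) -> str:  # e.g. "A:TYR55" or "B:GLY10A"
        return f"{self.chain_id}:{self.res_name}{self.res_seq}{self.i_code}"


@dataclass
class Atom:
    """One atom of a frame (coordinates in Angstrom)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    is_heavy: bool
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Frame:
    """One snapshot: residues with atoms, each residue assigned to a partner."""

    index: int
    residues: dict[ResidueKey, list[Atom]]
    partner_of: dict[ResidueKey, str]

    def residues_of(self, partner: str) -> list[ResidueKey]:
        keys = [k for k, p in self.partner_of.items() if p == partner]
        return sorted(keys)

    def heavy_atoms(self, partner: str) -> tuple[np.ndarray, list[ResidueKey], list[Atom]]:
        """Heavy-atom coordinates of one partner.

        Returns ``(coords, owner_keys, atoms)`` where ``owner_keys[i]`` is the
        residue owning coordinate row ``i``.
        """
        coords: list[np.ndarray] = []
        owners: list[ResidueKey] = []
        atoms: list[Atom] = []
        for key in self.residues_of(partner):
            for atom in self.residues[key]:
                if atom.is_heavy:
                    coords.append(atom.coords)
                    owners.append(key)
                    atoms.append(atom)
        if not coords:
            return np.empty((0, 3)), owners, atoms
        return np.asarray(coords), owners, atoms

    def validate(self) -> None:
        partners = set(self.partner_of.values())
        if partners - {"A", "B"}:
            raise ValueError(f"unknown partner labels: {partners - {'A', 'B'}}")
        for partner in ("A", "B"):
            if partner not in partners:
                raise EmptyPartnerError(
                    f"frame {self.index}: partner {partner} has no residues"
                )

    def swapped(self) -> "Frame":
        """Same frame with partner labels A and B exchanged."""
        flip = {"A": "B", "B": "A"}
        return Frame(
            index=self.index,
            residues=dict(self.residues),
            partner_of={k: flip[p] for k, p in self.partner_of.items()},
        )


@dataclass
class Trajectory:
    """Ordered frames plus the union residue registry per partner."""

    frames: list[Frame]
    remarks: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def registry(self, partner: str) -> list[ResidueKey]:
        seen: dict[ResidueKey, ResidueKey] = {}
        for frame in self.frames:
            for key in frame.residues_of(partner):
                seen.setdefault(key, key)
        return sorted(seen)

    def validate(self) -> None:
        if not self.frames:
            raise NoModelsError("trajectory has zero frames")
        overlap = set(self.registry("A")) & set(self.registry("B"))
        if overlap:
            raise ChainSelectionError(f"residues assigned to both partners: {overlap}")

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __len__(self) -> int:
        return self.n_frames


def _element_of(bio_atom) -> str:
    element = (bio_atom.element or "").strip().upper()
    if not element:
        # PDB atom-name convention: columns 13-14 hold the element, so a
        # name like " CA " is carbon while "CA  " would be calcium.
        name = bio_atom.get_fullname()
        element = name[:2].strip().lstrip("0123456789").upper()
        if len(element) == 2 and element[0] == "H":
            element = "H"
    return element


def _pick_altloc(bio_atom):
    """Resolve a possibly disordered atom to one conformer by occupancy."""
    if not bio_atom.is_disordered():
        return bio_atom
    conformers = bio_atom.disordered_get_list()
    best = conformers[0]
    for cand in conformers[1:]:
        if (cand.get_occupancy() or 0.0) > (best.get_occupancy() or 0.0):
            best = cand
    return best


def _frame_from_model(
    model,
    chains_a: frozenset[str],
    chains_b: frozenset[str],
    include_het: bool,
    index: int,
) -> Frame:
    residues: dict[ResidueKey, list[Atom]] = {}
    partner_of: dict[ResidueKey, str] = {}
    for chain in model:
        chain_id = chain.id
        if chain_id in chains_a:
            partner = "A"
        elif chain_id in chains_b:
            partner = "B"
        else:
            continue
        for res in chain:
            hetfield, res_seq, i_code = res.id
            res_name = res.get_resname().strip()
            if hetfield == "W" or res_name in _WATER_NAMES:
                continue
            if hetfield.startswith("H") and not include_het and res_name != "MSE":
                continue
            key = ResidueKey(chain_id, res_seq, i_code.strip(), res_name)
            atoms = residues.setdefault(key, [])
            partner_of[key] = partner
            for bio_atom in res:
                picked = _pick_altloc(bio_atom)
                element = _element_of(picked)
                atoms.append(
                    Atom(
                        serial=picked.get_serial_number() or 0,
                        name=picked.get_name(),
                        element=element,
                        coords=np.array(picked.get_coord(), dtype=float),
                        is_heavy=element not in _HYDROGEN_ELEMENTS,
                        occupancy=picked.get_occupancy() or 1.0,
                        alt_loc=(picked.get_altloc() or "").strip(),
                    )
                )
    return Frame(index=index, residues=residues, partner_of=partner_of)


def _parse_models(path: Path):
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(path.stem, str(path))
    return list(structure)


def _check_chain_args(chains_a: Iterable[str], chains_b: Iterable[str]):
    set_a, set_b = frozenset(chains_a), frozenset(chains_b)
    if not set_a or not set_b:
        raise ChainSelectionError("both partners need at least one chain ID")
    if set_a & set_b:
        raise ChainSelectionError(f"chains assigned to both partners: {sorted(set_a & set_b)}")
    return set_a, set_b


def read_multimodel_pdb(
    path: str | Path,
    chains_a: Iterable[str],
    chains_b: Iterable[str],
    include_het: bool = False,
) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    One frame per MODEL block, in file order; a file without MODEL records is
    a single-frame trajectory.
    """
    path = Path(path)
    set_a, set_b = _check_chain_args(chains_a, chains_b)
    if not path.is_file():
        raise MissingInputError(f"no such structure file: {path}")
    models = _parse_models(path)
    if not models:
        raise NoModelsError(f"{path}: no parseable model")
    frames = []
    for i, model in enumerate(models):
        frame = _frame_from_model(model, set_a, set_b, include_het, index=i)
        if frame.residues:
            frames.append(frame)
    if not frames:
        present = sorted({c.id for m in models for c in m})
        if present:
            raise ChainSelectionError(
                f"{path}: requested chains match nothing; file has chains {present}"
            )
        raise NoModelsError(f"{path}: no parseable model contains any chain")
    _check_partner_presence(frames, path)
    for i, frame in enumerate(frames):
        frame.index = i
    traj = Trajectory(frames=frames)
    traj.validate()
    return traj


def read_snapshot_set(
    paths: Sequence[str | Path],
    chains_a: Iterable[str],
    chains_b: Iterable[str],
    include_het: bool = False,
) -> Trajectory:
    """Read an ordered list of single-model snapshot files into one trajectory."""
    if not paths:
        raise MissingInputError("empty snapshot list")
    set_a, set_b = _check_chain_args(chains_a, chains_b)
    frames: list[Frame] = []
    for i, raw in enumerate(paths):
        path = Path(raw)
        if not path.is_file():
            raise MissingInputError(f"snapshot {i}: no such file: {path}")
        models = _parse_models(path)
        if not models:
            raise NoModelsError(f"snapshot {i} ({path}): no parseable model")
        if len(models) > 1:
            raise NoModelsError(
                f"snapshot {i} ({path}): expected a single model, found {len(models)}"
            )
        frame = _frame_from_model(models[0], set_a, set_b, include_het, index=i)
        if not frame.residues:
            raise NoModelsError(f"snapshot {i} ({path}): no atoms in the requested chains")
        frame.validate()
        frames.append(frame)
    traj = Trajectory(frames=frames)
    traj.validate()
    return traj


def _check_partner_presence(frames: list[Frame], path: Path) -> None:
    for frame in frames:
        try:
            frame.validate()
        except EmptyPartnerError as exc:
            raise EmptyPartnerError(f"{path}: {exc}") from exc


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as a canonical multi-model PDB (3-decimal Angstrom).

    The inverse of :func:`read_multimodel_pdb` up to coordinate precision;
    used for fixture generation and for exporting filtered ensembles.
    """
    path = Path(path)
    lines: list[str] = [f"REMARK   6 {r}" for r in traj.remarks]
    for frame in traj.frames:
        lines.append(f"MODEL     {frame.index + 1:>4d}")
        serial = 0
        for key in sorted(frame.residues):
            for atom in frame.residues[key]:
                serial += 1
                name = atom.name
                # standard alignment: 1-3 char names start in column 14
                fname = f" {name:<3s}" if len(name) < 4 else name[:4]
                lines.append(
                    f"ATOM  {serial:>5d} {fname}{atom.alt_loc or ' ':1s}"
                    f"{key.res_name:>3s} {key.chain_id:1s}{key.res_seq:>4d}"
                    f"{key.i_code or ' ':1s}   "
                    f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2s}"
                )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
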