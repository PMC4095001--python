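"""Contact typing by residue polarity and residue-pair distance monitoring.

The polarity dialect follows the COCOMAPS convention: nine hydrophobic
residues (ALA, VAL, LEU, ILE, MET, PHE, PRO, TRP, GLY) and eleven
hydrophilic ones (SER, THR, CYS, TYR, ASN, GLN, ASP, GLU, LYS, ARG, HIS).
The mapping is a plain two-column text config so the dialect can be swapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .conservation_stats import ContactRecord
from .errors import SelectionError
from .structure_io import Frame, ResidueKey, Trajectory

HH = "hydrophilic-hydrophilic"
PP = "hydrophobic-hydrophobic"
MIXED = "mixed"


def _default_table() -> dict[str, str]:
    table: dict[str, str] = {}
    text = resources.files("mdcons.data").joinpath("polarity_cocomaps.txt").read_text()
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            res, cls = line.split()
            table[res.upper()] = cls.lower()
    return table


@dataclass
class PolarityClass:
    """Residue-name -> {hydrophobic, hydrophilic} mapping."""

    table: dict[str, str] = field(default_factory=_default_table)
    default: str = "hydrophilic"
    strict: bool = False

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "PolarityClass":
        table: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if line:
                res, polarity = line.split()
                if polarity.lower() not in {"hydrophobic", "hydrophilic"}:
                    raise ValueError(f"bad polarity class {polarity!r} for {res}")
                table[res.upper()] = polarity.lower()
        return cls(table=table, **kwargs)

    def of(self, res_name: str) -> str:
        try:
            return self.table[res_name.upper()]
        except KeyError:
            if self.strict:
                raise SelectionError(f"unclassifiable residue name {res_name!r}") from None
            warnings.warn(
                f"residue {res_name!r} not in the polarity table; "
                f"defaulting to {self.default}",
                stacklevel=2,
            )
            return self.default


def classify_contact_types(
    records: Sequence[ContactRecord], polarity: PolarityClass | None = None
) -> dict[str, int]:
    """Partition contact records into the three polarity classes.

    Returns counts for hydrophilic-hydrophilic, hydrophobic-hydrophobic and
    mixed pairs; the counts always sum to ``len(records)``.
    """
    polarity = polarity or PolarityClass()
    counts = {HH: 0, PP: 0, MIXED: 0}
    for rec in records:
        pa = polarity.of(rec.key_a.res_name)
        pb = polarity.of(rec.key_b.res_name)
        if pa == pb == "hydrophilic":
            counts[HH] += 1
        elif pa == pb == "hydrophobic":
            counts[PP] += 1
        else:
            counts[MIXED] += 1
    return counts


@dataclass(frozen=True)
class Selection:
    """Atoms of one residue (optionally restricted to named atoms).

    Atom-name lists make "functional group" monitors explicit — e.g. the
    carboxylate of an aspartate is ``atom_names=("OD1", "OD2")`` and a lysine
    amino group ``("NZ",)`` — rather than inferred chemistry.
    """

    chain_id: str
    res_seq: int
    i_code: str = ""
    atom_names: tuple[str, ...] = ()

    def coords_in(self, frame: Frame) -> np.ndarray:
        key = ResidueKey(self.chain_id, self.res_seq, self.i_code)
        atoms = frame.residues.get(key)
        if atoms is None:
            return np.empty((0, 3))
        picked = [
            a.coords
            for a in atoms
            if a.is_heavy and (not self.atom_names or a.name in self.atom_names)
        ]
        return np.asarray(picked) if picked else np.empty((0, 3))

    def partner_in(self, frame: Frame) -> str | None:
        return frame.partner_of.get(ResidueKey(self.chain_id, self.res_seq, self.i_code))


@dataclass
class DistanceSeries:
    """Per-frame minimum heavy-atom distance between two selections."""

    selection_a: Selection
    selection_b: Selection
    per_frame_min: list[float]  # NaN where a selection is empty in that frame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": range(len(self.per_frame_min)),
             "min_distance_A": [round(d, 3) if np.isfinite(d) else np.nan
                                for d in self.per_frame_min]}
        )

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")
        return path


def min_distance_series(
    traj: Trajectory, selection_a: Selection, selection_b: Selection
) -> DistanceSeries:
    """Monitor the minimum distance between two residue selections over time."""
    traj.validate()
    partners_a = {selection_a.partner_in(f) for f in traj} - {None}
    partners_b = {selection_b.partner_in(f) for f in traj} - {None}
    if partners_a and partners_b and partners_a == partners_b:
        raise SelectionError("the two selections must target distinct partners")
    minima: list[float] = []
    any_pair = False
    for frame in traj:
        ca = selection_a.coords_in(frame)
        cb = selection_b.coords_in(frame)
        if len(ca) == 0 or len(cb) == 0:
            minima.append(float("nan"))
            continue
        diff = ca[:, None, :] - cb[None, :, :]
        minima.append(float(np.sqrt((diff * diff).sum(axis=-1)).min()))
        any_pair = True
    if not any_pair:
        raise SelectionError("selections are empty in every frame")
    return DistanceSeries(selection_a, selection_b, minima)
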