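"""Solvent-accessible surface areas and interface burial.

The interface area of a two-partner complex is defined as half of the
solvent-accessible surface area (ASA) buried upon complex formation:

    interface_area = (ASA(A) + ASA(B) - ASA(AB)) / 2

where the isolated-partner terms are computed by deleting the other
partner's atoms from the same coordinates (no re-relaxation).

ASA is computed with the Shrake-Rupley sphere-sampling method: each heavy
atom's van der Waals sphere is inflated by the probe radius (1.4 A, a water
molecule) and sampled with a deterministic golden-section spiral lattice of
``n_sphere_points`` points; a point is buried when it falls strictly inside
any neighbour's inflated sphere.  The lattice is fixed, so results are
bit-for-bit reproducible for fixed parameters — there is no random number
generator anywhere in this module.

Atom radii follow the Chothia (1976) set used by NACCESS: N 1.65, O 1.40,
S 1.85, tetrahedral C 1.87, trigonal/aromatic C 1.76; hydrogens have no
surface and do not occlude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptyPartnerError, UnknownAtomError
from .structure_io import Atom, Frame, ResidueKey, Trajectory

# Side-chain carbons that are sp2 (trigonal/aromatic) in the 20 standard
# residues; backbone carbonyl C is handled separately.  Everything else
# carbon is tetrahedral.
_SP2_CARBONS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"CZ"}),
    "ASN": frozenset({"CG"}),
    "ASP": frozenset({"CG"}),
    "GLN": frozenset({"CD"}),
    "GLU": frozenset({"CD"}),
    "HIS": frozenset({"CG", "CD2", "CE1"}),
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
}

_ELEMENT_FALLBACK = {
    "C": 1.76,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "SE": 1.90,
    "P": 1.80,
}


@dataclass(frozen=True)
class RadiiSet:
    """A van der Waals radius dialect.

    ``chothia()`` is the NACCESS-style default; ``from_file`` loads a plain
    two-column ``ELEMENT radius`` table to override the element fallbacks.
    """

    name: str = "chothia"
    element_radii: dict = field(default_factory=lambda: dict(_ELEMENT_FALLBACK))
    typed_carbons: bool = True

    @classmethod
    def chothia(cls) -> "RadiiSet":
        return cls()

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "RadiiSet":
        radii = dict(_ELEMENT_FALLBACK)
        path = Path(path)
        for raw in path.read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            element, value = line.split()
            radii[element.upper()] = float(value)
        return cls(name=name or path.stem, element_radii=radii, typed_carbons=False)

    def radius(self, res_name: str, atom: Atom) -> float:
        """Radius for one heavy atom; raises for unresolvable elements."""
        element = atom.element.upper()
        if element == "C" and self.typed_carbons:
            if atom.name == "C":  # backbone carbonyl
                return 1.76
            if atom.name in _SP2_CARBONS.get(res_name, frozenset()):
                return 1.76
            return 1.87
        try:
            return self.element_radii[element]
        except KeyError:
            raise UnknownAtomError(
                f"no radius for atom {atom.name} (element {element!r}) in {res_name}"
            ) from None


@dataclass
class SasaParams:
    """Probe radius (A), sphere sampling density, and radius dialect."""

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii: RadiiSet = field(default_factory=RadiiSet.chothia)

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 100:
            raise ValueError("n_sphere_points must be at least 100")


@dataclass
class AreaSeries:
    """Per-frame interface areas with mean and sample standard deviation."""

    per_frame_area: list[float]
    reference_area: float | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_frame_area))

    @property
    def sd(self) -> float:
        if len(self.per_frame_area) < 2:
            return 0.0
        return float(np.std(self.per_frame_area, ddof=1))

    @property
    def sd_defined(self) -> bool:
        return len(self.per_frame_area) >= 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": range(len(self.per_frame_area)),
             "interface_area_A2": [round(a, 2) for a in self.per_frame_area]}
        )

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            self.to_frame().to_csv(fh, sep="\t", index=False)
            fh.write(f"# mean\t{self.mean:.2f}\n# sd\t{self.sd:.2f}\n")
            if not self.sd_defined:
                fh.write("# sd undefined for a single frame (reported as 0)\n")
            if self.reference_area is not None:
                fh.write(f"# reference\t{self.reference_area:.2f}\n")
        return path


@dataclass
class BurialRow:
    key: ResidueKey
    asa_free: float
    asa_complex: float
    pct_buried: float
    flagged: bool  # asa_free below the floor; pct not meaningful


@dataclass
class BurialReport:
    """Per-residue free-vs-complex ASA and percent burial."""

    rows: list[BurialRow]
    asa_floor: float = 0.1

    def by_key(self) -> dict[ResidueKey, BurialRow]:
        return {r.key: r for r in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chain": r.key.chain_id,
                    "resnum": f"{r.key.res_seq}{r.key.i_code}",
                    "resname": r.key.res_name,
                    "asa_free": round(r.asa_free, 2),
                    "asa_complex": round(r.asa_complex, 2),
                    "pct_buried": round(r.pct_buried, 1),
                    "flagged": r.flagged,
                }
                for r in self.rows
            ]
        )

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral lattice on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_sasa(
    coords: np.ndarray, radii: np.ndarray, params: SasaParams | None = None
) -> np.ndarray:
    """Per-atom accessible areas (A^2) via Shrake-Rupley sampling.

    ``coords`` is (n, 3) and ``radii`` the matching van der Waals radii of
    heavy atoms only; the probe radius is added internally.
    """
    params = params or SasaParams()
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    inflated = radii + params.probe_radius
    unit = sphere_points(params.n_sphere_points)
    tree = cKDTree(coords)
    r_max = inflated.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + inflated[i] * unit
        accessible = np.ones(params.n_sphere_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], inflated[i] + r_max):
            if j == i:
                continue
            rj = inflated[j]
            if np.dot(coords[i] - coords[j], coords[i] - coords[j]) >= (inflated[i] + rj) ** 2:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 >= rj * rj
            if not accessible.any():
                break
        areas[i] = 4.0 * math.pi * inflated[i] ** 2 * accessible.sum() / params.n_sphere_points
    return areas


def _heavy_selection(
    frame: Frame, partners: Sequence[str], params: SasaParams
) -> tuple[np.ndarray, np.ndarray, list[ResidueKey]]:
    coords, radii, owners = [], [], []
    for partner in partners:
        for key in frame.residues_of(partner):
            for atom in frame.residues[key]:
                if not atom.is_heavy:
                    continue  # NACCESS convention: hydrogens neither count nor occlude
                coords.append(atom.coords)
                radii.append(params.radii.radius(key.res_name, atom))
                owners.append(key)
    if not coords:
        raise EmptyPartnerError(f"frame {frame.index}: no heavy atoms in partners {partners}")
    return np.asarray(coords), np.asarray(radii), owners


def total_sasa(frame: Frame, partners: Sequence[str], params: SasaParams | None = None) -> float:
    """Total ASA (A^2) of the named selection computed in isolation."""
    params = params or SasaParams()
    coords, radii, _ = _heavy_selection(frame, partners, params)
    return float(atom_sasa(coords, radii, params).sum())


def interface_area(frame: Frame, params: SasaParams | None = None) -> float:
    """Half the ASA buried on complexation, in A^2."""
    params = params or SasaParams()
    frame.validate()
    asa_a = total_sasa(frame, ["A"], params)
    asa_b = total_sasa(frame, ["B"], params)
    asa_ab = total_sasa(frame, ["A", "B"], params)
    return (asa_a + asa_b - asa_ab) / 2.0


def area_series(
    traj: Trajectory,
    params: SasaParams | None = None,
    reference_area: float | None = None,
    progress=None,
) -> AreaSeries:
    """Interface area of every frame of the trajectory."""
    params = params or SasaParams()
    traj.validate()
    areas = []
    for frame in traj:
        areas.append(interface_area(frame, params))
        if progress is not None:
            progress(frame.index)
    return AreaSeries(per_frame_area=areas, reference_area=reference_area)


def residue_burial(
    frame: Frame, params: SasaParams | None = None, asa_floor: float = 0.1
) -> BurialReport:
    """Per-residue ASA in the isolated partner vs in the complex.

    Residues whose free ASA falls below ``asa_floor`` (fully interior
    residues) are flagged instead of divided.
    """
    params = params or SasaParams()
    frame.validate()

    def per_residue(partners: Sequence[str]) -> dict[ResidueKey, float]:
        coords, radii, owners = _heavy_selection(frame, partners, params)
        areas = atom_sasa(coords, radii, params)
        acc: dict[ResidueKey, float] = {}
        for key, area in zip(owners, areas):
            acc[key] = acc.get(key, 0.0) + float(area)
        return acc

    free = per_residue(["A"])
    free.update(per_residue(["B"]))
    complexed = per_residue(["A", "B"])
    rows = []
    for key in sorted(free):
        asa_free = free[key]
        asa_cx = complexed.get(key, 0.0)
        if asa_free < asa_floor:
            rows.append(BurialRow(key, asa_free, asa_cx, 0.0, flagged=True))
        else:
            pct = 100.0 * (asa_free - asa_cx) / asa_free
            rows.append(BurialRow(key, asa_free, asa_cx, pct, flagged=False))
    return BurialReport(rows=rows, asa_floor=asa_floor)
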