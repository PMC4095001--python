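"""Contact conservation across an ensemble.

For each residue pair (k, l) — k on partner A, l on partner B — seen in at
least one frame, the conservation rate is

    CR_kl = nc_kl / N

with nc_kl the number of frames containing the contact and N the number of
analysed frames, so CR_kl = 1 for a contact present in every frame.  The
overall-conservation coefficients are, for a threshold t in {0.50, 0.70,
0.90},

    C_t = nc_t / (sum_i nc_i / N)

where nc_t counts the distinct contacts conserved in at least a fraction t
of the frames (inclusive threshold) and the denominator is the mean number
of contacts per frame.  Note the two counts live on different footings —
distinct pairs versus a per-frame average — so C_t is not bounded by 1 and
is deliberately not clipped.

Threshold comparisons are carried out in exact rational arithmetic
(nc_kl / N >= t as fractions), so a contact conserved in exactly 70% of the
frames counts toward nc_70 regardless of binary floating-point rounding.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .contact_detection import ContactSet, Pair
from .errors import NoContactsError, RegistryError
from .structure_io import ResidueKey

DEFAULT_THRESHOLDS = (0.50, 0.70, 0.90)


@dataclass(frozen=True)
class ContactRecord:
    """One residue pair with its frame count and conservation rate."""

    pair: Pair
    nc_kl: int
    cr_kl: float

    @property
    def key_a(self) -> ResidueKey:
        return self.pair[0]

    @property
    def key_b(self) -> ResidueKey:
        return self.pair[1]


@dataclass
class ConsensusMatrix:
    """Dense CR matrix over the partner registries (0 = never in contact)."""

    row_keys: list[ResidueKey]  # partner A
    col_keys: list[ResidueKey]  # partner B
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=[str(k) for k in self.row_keys],
            columns=[str(k) for k in self.col_keys],
        )

    def write_text(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep=" ", float_format="%.4f")
        return path


@dataclass
class ConservationSummary:
    """N, per-frame contact counts, and the threshold coefficients."""

    n_frames: int
    nc_per_frame: list[int]
    thresholds: tuple[float, ...]
    nc_at_threshold: dict[float, int]
    coefficients: dict[float, float]

    @property
    def mean_nc(self) -> float:
        return sum(self.nc_per_frame) / self.n_frames

    def to_text(self) -> str:
        lines = [
            f"N_frames\t{self.n_frames}",
            f"mean_contacts_per_frame\t{self.mean_nc:.2f}",
        ]
        for t in self.thresholds:
            pct = int(round(t * 100))
            lines.append(
                f"C_{pct}\t{self.coefficients[t]:.2f}\tnc_{pct}\t{self.nc_at_threshold[t]}"
            )
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_text())
        return path


def _sort_key(pair: Pair):
    ka, kb = pair
    return (ka.chain_id, ka.res_seq, ka.i_code, kb.chain_id, kb.res_seq, kb.i_code)


def conservation_rates(
    contact_sets: Sequence[ContactSet], n_frames: int | None = None
) -> list[ContactRecord]:
    """One :class:`ContactRecord` per pair observed in at least one frame.

    Pairs never in contact yield no record (their CR of zero is represented
    only implicitly, as an empty cell of the consensus matrix).
    """
    if not contact_sets:
        raise NoContactsError("no contact sets supplied")
    n = n_frames if n_frames is not None else len(contact_sets)
    if n != len(contact_sets):
        raise ValueError(f"n_frames={n} but {len(contact_sets)} contact sets given")
    counts: Counter[Pair] = Counter()
    for cs in contact_sets:
        counts.update(cs.pairs.keys())
    return [
        ContactRecord(pair=pair, nc_kl=c, cr_kl=c / n)
        for pair, c in sorted(counts.items(), key=lambda kv: _sort_key(kv[0]))
    ]


def conservation_coefficients(
    records: Sequence[ContactRecord],
    nc_per_frame: Sequence[int],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> ConservationSummary:
    """The C_t coefficients for the given conservation thresholds."""
    n = len(nc_per_frame)
    if n < 1:
        raise NoContactsError("nc_per_frame is empty")
    total = int(sum(nc_per_frame))
    if total == 0:
        raise NoContactsError("no contacts in any frame; coefficients are undefined")
    for t in thresholds:
        if not 0 < t <= 1:
            raise ValueError(f"threshold {t} outside (0, 1]")
    mean_nc = Fraction(total, n)
    nc_at: dict[float, int] = {}
    coeffs: dict[float, float] = {}
    for t in thresholds:
        t_exact = Fraction(str(t))
        nc_t = sum(1 for r in records if Fraction(r.nc_kl, n) >= t_exact)
        nc_at[t] = nc_t
        coeffs[t] = float(Fraction(nc_t) / mean_nc)
    return ConservationSummary(
        n_frames=n,
        nc_per_frame=list(int(x) for x in nc_per_frame),
        thresholds=tuple(thresholds),
        nc_at_threshold=nc_at,
        coefficients=coeffs,
    )


def consensus_matrix(
    records: Sequence[ContactRecord],
    registry_a: Sequence[ResidueKey],
    registry_b: Sequence[ResidueKey],
) -> ConsensusMatrix:
    """Dense CR matrix, rows = partner A registry, columns = partner B registry."""
    rows = sorted(registry_a)
    cols = sorted(registry_b)
    row_idx = {k: i for i, k in enumerate(rows)}
    col_idx = {k: i for i, k in enumerate(cols)}
    values = np.zeros((len(rows), len(cols)))
    for rec in records:
        ka, kb = rec.pair
        if ka not in row_idx or kb not in col_idx:
            raise RegistryError(f"contact pair ({ka}, {kb}) not covered by the registry")
        values[row_idx[ka], col_idx[kb]] = rec.cr_kl
    return ConsensusMatrix(row_keys=rows, col_keys=cols, values=values)


def records_table(records: Sequence[ContactRecord]) -> pd.DataFrame:
    """Contact-record table with CR reported at 2 decimals."""
    rows = [
        {
            "chain_A": r.key_a.chain_id,
            "resnum_A": f"{r.key_a.res_seq}{r.key_a.i_code}",
            "resname_A": r.key_a.res_name,
            "chain_B": r.key_b.chain_id,
            "resnum_B": f"{r.key_b.res_seq}{r.key_b.i_code}",
            "resname_B": r.key_b.res_name,
            "nc_kl": r.nc_kl,
            "CR_kl": round(r.cr_kl, 2),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chain_A", "resnum_A", "resname_A",
            "chain_B", "resnum_B", "resname_B", "nc_kl", "CR_kl",
        ],
    )


def write_records_tsv(records: Sequence[ContactRecord], path: str | Path) -> Path:
    path = Path(path)
    records_table(records).to_csv(path, sep="\t", index=False)
    return path
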