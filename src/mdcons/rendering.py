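"""Grayscale consensus contact maps.

Each contact is drawn as one mark at (residue of partner A, residue of
partner B); the mark's gray level encodes the conservation rate, from white
(never in contact, no mark) to pure black (present in every frame).  A
single structure is rendered through the same code path as the degenerate
N = 1 consensus of itself, so the two renderings are pixel-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .conservation_stats import ConsensusMatrix, conservation_rates, consensus_matrix
from .contact_detection import ContactSet


@dataclass
class MapStyle:
    """Appearance of a consensus map.

    ``gamma`` < 1 darkens weakly conserved contacts that would otherwise
    vanish at small marker sizes; the gray level is ``1 - cr**gamma``, which
    is strictly decreasing in CR for any positive gamma (darker = more
    conserved).
    """

    gamma: float = 1.0
    marker_size: float = 25.0
    marker: str = "s"
    a_on_x: bool = True
    dpi: int = 150
    figsize: tuple[float, float] = (6.0, 6.0)

    def gray_level(self, cr: float) -> float:
        if not 0.0 <= cr <= 1.0:
            raise ValueError(f"conservation rate {cr} outside [0, 1]")
        return 1.0 - cr ** self.gamma


def _axis_label(keys) -> str:
    chains = sorted({k.chain_id for k in keys})
    return f"partner residues (chain {', '.join(chains)})" if chains else "residues"


def render_consensus_map(
    matrix: ConsensusMatrix, style: MapStyle | None = None, out_path: str | Path = "consensus_map.png"
) -> Path:
    """Render the grayscale consensus map to PNG or SVG (by extension)."""
    style = style or MapStyle()
    if not matrix.row_keys or not matrix.col_keys:
        raise ValueError("degenerate consensus matrix: empty registry on one axis")
    out_path = Path(out_path)

    xs, ys, grays = [], [], []
    for i, ka in enumerate(matrix.row_keys):
        for j, kb in enumerate(matrix.col_keys):
            cr = matrix.values[i, j]
            if cr <= 0:
                continue
            a_pos, b_pos = ka.res_seq, kb.res_seq
            x, y = (a_pos, b_pos) if style.a_on_x else (b_pos, a_pos)
            xs.append(x)
            ys.append(y)
            g = style.gray_level(cr)
            grays.append((g, g, g))

    fig, ax = plt.subplots(figsize=style.figsize, dpi=style.dpi)
    if xs:
        marks = ax.scatter(xs, ys, s=style.marker_size, c=grays, marker=style.marker,
                           edgecolors="none")
        marks.set_gid("contact-marks")  # addressable group in SVG output
    a_keys, b_keys = matrix.row_keys, matrix.col_keys
    x_keys, y_keys = (a_keys, b_keys) if style.a_on_x else (b_keys, a_keys)
    ax.set_xlim(min(k.res_seq for k in x_keys) - 1, max(k.res_seq for k in x_keys) + 1)
    ax.set_ylim(min(k.res_seq for k in y_keys) - 1, max(k.res_seq for k in y_keys) + 1)
    ax.set_xlabel(_axis_label(x_keys))
    ax.set_ylabel(_axis_label(y_keys))
    ax.set_title("consensus contact map")
    fig.tight_layout()
    try:
        fig.savefig(out_path)
    finally:
        plt.close(fig)
    return out_path


def render_contact_map(
    contacts: ContactSet, style: MapStyle | None = None, out_path: str | Path = "contact_map.png"
) -> Path:
    """Render a single structure's contact map (all marks full black)."""
    records = conservation_rates([contacts], n_frames=1)
    reg_a = sorted({r.key_a for r in records})
    reg_b = sorted({r.key_b for r in records})
    if not records:
        # blank axes: fall back to a degenerate one-cell zero matrix
        fig, ax = plt.subplots(figsize=(style or MapStyle()).figsize,
                               dpi=(style or MapStyle()).dpi)
        ax.set_title("consensus contact map")
        out_path = Path(out_path)
        fig.savefig(out_path)
        plt.close(fig)
        return out_path
    matrix = consensus_matrix(records, reg_a, reg_b)
    return render_consensus_map(matrix, style, out_path)
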