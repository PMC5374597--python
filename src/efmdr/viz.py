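"""Membership-shaded interaction plots.

Each genotype cell shows a left bar (case count) and a right bar
(control count), both annotated, over a background shaded by the cell's
high-risk membership: red for mu_H > 0.5, green for mu_H < 0.5, white in
a configurable band around 0.5, with saturation increasing linearly in
|mu_H - 0.5|.  Genotypes are labelled with allele letters, uppercase for
the major and lowercase for the minor allele (0 = "AA", 1 = "Aa",
2 = "aa").  A three-locus model is drawn as three side-by-side two-locus
panels, one per genotype of the third SNP.  Every figure is accompanied
by a structured render log so results can be checked on data, not
pixels.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .data import CellTable
from .membership import MembershipAssignment

_RED = np.array([0.839, 0.153, 0.157])
_GREEN = np.array([0.173, 0.627, 0.173])
_NEUTRAL = "#f0f0f0"


class LayoutError(ValueError):
    """Unsupported panel layout."""


def cell_color(mu_h: float, white_band: float = 0.05) -> str:
    """Hex background colour for a membership degree.

    Linear interpolation from white toward red (high risk) or green
    (low risk); degrees within ``white_band`` of 0.5 stay white.
    """
    if np.isnan(mu_h):
        return _NEUTRAL
    dev = mu_h - 0.5
    if abs(dev) <= white_band:
        return "#ffffff"
    target = _RED if dev > 0 else _GREEN
    sat = (abs(dev) - white_band) / (0.5 - white_band)
    rgb = (1 - sat) + sat * target
    return "#{:02x}{:02x}{:02x}".format(*(np.round(rgb * 255).astype(int)))


def genotype_label(geno: tuple[int, ...], letters: str | None = None) -> str:
    """Allele-letter label: uppercase major, lowercase minor."""
    letters = letters or string.ascii_uppercase
    parts = []
    for j, g in enumerate(geno):
        up, lo = letters[j], letters[j].lower()
        parts.append({0: up + up, 1: up + lo, 2: lo + lo}[g])
    return "/".join(parts)


@dataclass
class InteractionPlotSpec:
    """What to draw: a counted table, its membership, and styling."""

    table: CellTable
    membership: MembershipAssignment
    snp_labels: tuple[str, ...] | None = None
    white_band: float = 0.05


def _render_log(spec: InteractionPlotSpec) -> list[dict]:
    table, m = spec.table, spec.membership
    log = []
    for i in range(table.n_cells):
        mu = float(m.mu_h[i]) if not m.empty[i] else float("nan")
        log.append(
            {
                "cell": i,
                "genotype": table.genotype_tuple(i),
                "label": genotype_label(table.genotype_tuple(i)),
                "n_case": int(table.n_case[i]),
                "n_control": int(table.n_control[i]),
                "mu_h": None if m.empty[i] else mu,
                "color": cell_color(mu, spec.white_band),
            }
        )
    return log


def _draw_cell(ax, entry: dict, ymax: float) -> None:
    ax.set_facecolor(entry["color"])
    n1, n0 = entry["n_case"], entry["n_control"]
    if n1 or n0:
        ax.bar([0.32, 0.68], [n1, n0], width=0.24, color=["#404040", "#b0b0b0"])
        ax.text(0.32, n1, str(n1), ha="center", va="bottom", fontsize=7)
        ax.text(0.68, n0, str(n0), ha="center", va="bottom", fontsize=7)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, ymax * 1.3 if ymax else 1)
    ax.set_xticks([])
    ax.set_yticks([])


def render_interaction(
    spec: InteractionPlotSpec,
    out_path: str | Path | None = None,
    log_path: str | Path | None = None,
):
    """Render the interaction plot; returns ``(figure, render_log)``.

    Pure function of the spec: the render log (cell, counts, membership,
    colour) is byte-identical across re-renders, and the image is written
    to ``out_path`` when given (format from the suffix, e.g. .png/.svg).
    """
    table = spec.table
    k = table.k
    if k not in (1, 2, 3):
        raise LayoutError(
            f"interaction plots support 1-3 loci, got order {k}; "
            "use the tabular export for higher orders"
        )
    if spec.membership.n_cells != table.n_cells:
        raise ValueError("membership does not match the table")
    log = _render_log(spec)
    ymax = float(max(table.n_case.max(), table.n_control.max()))
    labels = spec.snp_labels or (
        table.snp_names or tuple(f"SNP{i + 1}" for i in table.snp_indices)
    )

    n_panels = 3 if k == 3 else 1
    nrow = 3 if k >= 2 else 1
    ncol = 3
    fig, axes = plt.subplots(
        nrow,
        ncol * n_panels,
        figsize=(2.0 * ncol * n_panels, 1.6 * nrow + 0.8),
        squeeze=False,
    )
    letters = string.ascii_uppercase
    for entry in log:
        geno = entry["genotype"]
        if k == 1:
            r, c, panel = 0, geno[0], 0
        elif k == 2:
            r, c, panel = geno[0], geno[1], 0
        else:
            r, c, panel = geno[0], geno[1], geno[2]
        ax = axes[r][panel * ncol + c]
        _draw_cell(ax, entry, ymax)
        if r == (nrow - 1):
            sub = geno[1] if k >= 2 else geno[0]
            j = 1 if k >= 2 else 0
            ax.set_xlabel(
                genotype_label((sub,), letters[j:]), fontsize=8
            )
        if c == 0 and panel == 0 and k >= 2:
            ax.set_ylabel(genotype_label((geno[0],)), fontsize=8)
    if k == 3:
        for panel in range(3):
            axes[0][panel * ncol + 1].set_title(
                f"{labels[2]} = {genotype_label((panel,), letters[2:])}", fontsize=9
            )
    fig.suptitle(" x ".join(labels[:k]), fontsize=10)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    if log_path is not None:
        Path(log_path).write_text(json.dumps(log, indent=1))
    return fig, log
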