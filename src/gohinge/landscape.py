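"""Potential-of-mean-force estimation from projected trajectories.

The PMF is the raw-histogram free energy of the equilibrium trajectory,
F(bin) = -k_B T ln(count / max_count) in kcal/mol, so the global minimum is
exactly zero and differences between bins are -k_B T times the log count
ratio. No reweighting is applied: the trajectory samples the mixed potential
directly. Empty bins are flagged (nan).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gomodel import KB_KCAL

DEFAULT_BINS = 40
RANGE_PADDING = 0.02
CONTOUR_SPACING = 0.5  # kcal/mol


@dataclass(frozen=True)
class PmfGrid:
    """Binned free-energy surface (1-D or 2-D)."""

    axes: tuple[str, ...]
    edges: tuple[np.ndarray, ...]
    free_energy: np.ndarray      # kcal/mol, min-shifted to 0; nan where empty
    counts: np.ndarray
    temperature: float
    annotations: dict = field(default_factory=dict)

    @property
    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    def to_tsv(self) -> str:
        lines = ["\t".join([f"{a}_center" for a in self.axes]
                           + ["free_energy_kcal_mol", "count"])]
        centers = self.centers
        if len(self.axes) == 1:
            for i, c in enumerate(centers[0]):
                f = self.free_energy[i]
                lines.append(f"{c:.6g}\t{'' if np.isnan(f) else f'{f:.6f}'}\t"
                             f"{int(self.counts[i])}")
        else:
            for i, cx in enumerate(centers[0]):
                for j, cy in enumerate(centers[1]):
                    f = self.free_energy[i, j]
                    lines.append(
                        f"{cx:.6g}\t{cy:.6g}\t"
                        f"{'' if np.isnan(f) else f'{f:.6f}'}\t"
                        f"{int(self.counts[i, j])}"
                    )
        return "\n".join(lines) + "\n"

    def plot(self, path, contour_spacing: float = CONTOUR_SPACING) -> None:
        """Write a PMF figure (line for 1-D, filled contours for 2-D)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        if len(self.axes) == 1:
            ax.plot(self.centers[0], self.free_energy)
            ax.set_xlabel(self.axes[0])
            ax.set_ylabel("F (kcal/mol)")
        else:
            fmax = np.nanmax(self.free_energy)
            levels = np.arange(0.0, fmax + contour_spacing, contour_spacing)
            cs = ax.contourf(self.centers[0], self.centers[1],
                             self.free_energy.T, levels=levels)
            fig.colorbar(cs, ax=ax, label="F (kcal/mol)")
            ax.set_xlabel(self.axes[0])
            ax.set_ylabel(self.axes[1])
        for label, (x, *rest) in self.annotations.items():
            y = rest[0] if rest else np.nanmax(self.free_energy)
            ax.annotate(label, (x, y), fontsize=12, fontweight="bold")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def pmf(
    x: np.ndarray,
    y: np.ndarray | None = None,
    temperature: float = 300.0,
    bins: int = DEFAULT_BINS,
    axis_names: tuple[str, ...] | None = None,
    labels: np.ndarray | None = None,
    label_series: dict[str, np.ndarray] | None = None,
) -> PmfGrid:
    """Histogram free energy along one or two coordinate series.

    Bin ranges are the observed range padded by 2%. If ``labels`` (O/TS/C
    per frame) is given, the mean position of each ensemble is stored as an
    annotation. All samples landing in a single bin triggers a
    degenerate-grid warning.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    x = np.asarray(x, dtype=float)
    series = [x]
    if y is not None:
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise ValueError("x and y series are not aligned")
        series.append(y)

    def padded_edges(s):
        lo, hi = s.min(), s.max()
        pad = (hi - lo) * RANGE_PADDING or 0.5
        return np.linspace(lo - pad, hi + pad, bins + 1)

    edges = tuple(padded_edges(s) for s in series)
    if y is None:
        counts, _ = np.histogram(x, bins=edges[0])
    else:
        counts, _, _ = np.histogram2d(x, y, bins=edges)
    if (counts > 0).sum() == 1:
        warnings.warn("all samples fall in a single bin: degenerate PMF grid")
    with np.errstate(divide="ignore"):
        f = -KB_KCAL * temperature * np.log(counts / counts.max())
    f = np.where(counts > 0, f, np.nan)
    names = axis_names or (("x",) if y is None else ("x", "y"))
    annotations = {}
    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        for ens in ("O", "TS", "C"):
            mask = labels == ens
            if mask.any():
                annotations[ens] = tuple(float(s[mask].mean()) for s in series)
    return PmfGrid(axes=tuple(names), edges=edges, free_energy=f,
                   counts=counts, temperature=temperature,
                   annotations=annotations)
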