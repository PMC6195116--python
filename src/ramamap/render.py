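"""Color schemes and image output for MAPs.

Two domain colormaps are provided on top of the standard matplotlib
ones:

* ``"Chirality"`` — diverging red/white/blue centered on ℛ = 0.5:
  right-twisting backbones (ℛ < 0.5) red, left-twisting (ℛ > 0.5)
  blue, mirroring the handedness flip across the positive diagonal of
  the Ramachandran plot.
* ``"SecondaryStructure"`` — band highlights at the canonical loci:
  α-helices (ℛ ≈ 0.34) red, β-sheets (ℛ ≈ 0.52) blue, ppII helices
  (ℛ ≈ 0.60) cyan, white elsewhere.

The anchor positions and colors are data, not code: override the
``stops`` of a :class:`ColorScheme` to retune them.  For signed maps
the same anchor layout is stretched over [−1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib import colormaps as mpl_colormaps
from matplotlib.colors import LinearSegmentedColormap

__all__ = ["ColorScheme", "get_scheme", "colormap_value", "draw_map", "CUSTOM_SCHEMES"]

# Anchor stops as (position within [0, 1] of the display range, RGB).
CUSTOM_SCHEMES: dict[str, list[tuple[float, tuple[float, float, float]]]] = {
    "Chirality": [
        (0.00, (0.55, 0.00, 0.00)),  # dark red: strongly right-twisting
        (0.50, (1.00, 1.00, 1.00)),
        (1.00, (0.00, 0.00, 0.55)),  # dark blue: strongly left-twisting
    ],
    "SecondaryStructure": [
        (0.00, (1.00, 1.00, 1.00)),
        (0.34, (0.85, 0.10, 0.10)),  # α-helix band
        (0.45, (1.00, 1.00, 1.00)),
        (0.52, (0.10, 0.10, 0.85)),  # β-sheet band
        (0.60, (0.10, 0.80, 0.85)),  # ppII band
        (1.00, (1.00, 1.00, 1.00)),
    ],
}


@dataclass
class ColorScheme:
    """A named colormap with an explicit display range.

    ``stops`` positions are fractions of [vmin, vmax]; ``mpl`` holds
    the interpolating matplotlib colormap.
    """

    name: str
    stops: list[tuple[float, tuple[float, float, float]]] | None
    vmin: float = 0.0
    vmax: float = 1.0
    _cmap: object = field(init=False, repr=False, default=None)

    def __post_init__(self):
        if self.stops is not None:
            positions = [p for p, _ in self.stops]
            if positions != sorted(set(positions)):
                raise ValueError("stop positions must be strictly increasing")
            self._cmap = LinearSegmentedColormap.from_list(self.name, self.stops)
        else:
            self._cmap = mpl_colormaps[self.name]
        # matplotlib copies are mutable; NaN cells render as background
        self._cmap = self._cmap.copy()
        self._cmap.set_bad((1.0, 1.0, 1.0, 0.0))

    @property
    def mpl(self):
        return self._cmap

    def normalize(self, value):
        return (np.asarray(value, dtype=float) - self.vmin) / (self.vmax - self.vmin)


def get_scheme(name: str, vmin: float = 0.0, vmax: float = 1.0) -> ColorScheme:
    """Look up a scheme by name: the domain schemes above, or any
    standard matplotlib colormap (``"Greys"``, ``"Reds"``, ...)."""
    stops = CUSTOM_SCHEMES.get(name)
    if stops is None and name not in mpl_colormaps:
        raise KeyError(
            f"unknown color scheme {name!r}; choose one of "
            f"{sorted(CUSTOM_SCHEMES)} or a matplotlib colormap"
        )
    return ColorScheme(name=name, stops=stops, vmin=vmin, vmax=vmax)


def colormap_value(value: float, scheme: ColorScheme) -> tuple[float, float, float]:
    """RGB triple for one value under a scheme.

    Values outside [vmin, vmax] are clamped with a warning; NaN maps to
    the transparent background color.
    """
    if np.isnan(value):
        return scheme.mpl.get_bad()[:3]
    if value < scheme.vmin or value > scheme.vmax:
        warnings.warn(
            f"value {value} outside display range "
            f"[{scheme.vmin}, {scheme.vmax}]; clamping"
        )
        value = min(max(value, scheme.vmin), scheme.vmax)
    frac = float(scheme.normalize(value))
    if scheme.stops is not None:
        # interpolate the anchor stops directly: exact at the anchors and
        # at analytic midpoints, unlike the 256-entry mpl lookup table
        positions = np.array([p for p, _ in scheme.stops])
        channels = np.array([c for _, c in scheme.stops])
        return tuple(
            float(np.interp(frac, positions, channels[:, k])) for k in range(3)
        )
    return tuple(float(c) for c in scheme.mpl(frac)[:3])


def _is_histogram_series(matrix: pd.DataFrame) -> bool:
    # histogram stacks index by ℛ bin centers (floats in [-1, 1]);
    # residue maps index by residue labels
    return matrix.index.name == "R"


def draw_map(
    matrix: pd.DataFrame,
    scheme: ColorScheme | str = "SecondaryStructure",
    xlabel: str = "Frame #",
    ylabel: str | None = None,
    zlabel: str = "ℛ",
    title: str | None = None,
    out: str | Path | None = None,
    dpi: int = 150,
):
    """Render a MAP matrix (residue map, deviation map or histogram
    series) to an image, with a CSV sidecar next to it.

    Frames run along the horizontal axis.  For residue maps the
    vertical axis is the residue label; for histogram stacks it is ℛ in
    [0, 1] (or [−1, 1] signed) with ticks every 0.2.  Undefined cells
    are left as background.  Returns the matplotlib figure.
    """
    import matplotlib

    if out is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if matrix.size == 0:
        raise ValueError("cannot draw an empty matrix")
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)

    values = matrix.to_numpy(dtype=float)
    histogram = _is_histogram_series(matrix)

    fig, ax = plt.subplots(figsize=(6, 4), constrained_layout=True)
    n_rows, n_cols = values.shape
    if histogram:
        edges_y = np.empty(n_rows + 1)
        centers = matrix.index.to_numpy(dtype=float)
        half = np.diff(centers).mean() / 2 if n_rows > 1 else 0.5
        edges_y[:-1] = centers - half
        edges_y[-1] = centers[-1] + half
    else:
        edges_y = np.arange(n_rows + 1) - 0.5
    edges_x = np.arange(n_cols + 1) - 0.5
    mesh = ax.pcolormesh(
        edges_x,
        edges_y,
        np.ma.masked_invalid(values),
        cmap=scheme.mpl,
        vmin=scheme.vmin,
        vmax=scheme.vmax,
    )
    ax.set_xlabel(xlabel)
    if ylabel is None:
        ylabel = zlabel if histogram else "Residue #"
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)

    # frame labels on the x axis, thinned to stay readable
    cols = list(matrix.columns)
    step_x = max(1, n_cols // 10)
    ax.set_xticks(np.arange(0, n_cols, step_x))
    ax.set_xticklabels([str(c) for c in cols[::step_x]])
    if histogram:
        lo = -1.0 if float(matrix.index.min()) < 0 else 0.0
        ax.set_yticks(np.arange(lo, 1.00001, 0.2))
    else:
        rows = list(matrix.index)
        step_y = max(1, n_rows // 15)
        ax.set_yticks(np.arange(0, n_rows, step_y))
        ax.set_yticklabels([str(r) for r in rows[::step_y]])
        ax.invert_yaxis()
    fig.colorbar(mesh, ax=ax, label=zlabel)

    if out is not None:
        out = Path(out)
        out.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out, dpi=dpi)
        matrix.to_csv(out.with_suffix(".csv"))
        plt.close(fig)
    return fig
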