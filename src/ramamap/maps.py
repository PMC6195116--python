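"""Stackable ℛ-code products: multi-angle pictures (MAPs).

A single structure collapses into a one-dimensional "ℛ-code" — either a
per-residue list of Ramachandran numbers or a histogram over ℛ space.
Stacking such codes side by side over the frames of an ensemble or
trajectory gives a matrix picture of the whole backbone's evolution:

* :func:`build_residue_map` — residue × frame matrix of ℛ (or ℛₛ);
* :func:`build_histogram_series` — per-frame normalized ℛ histograms
  P′(ℛ), the "topology over time" view;
* :func:`build_deviation_map` — residue × frame matrix of D₁ or D₋₁;
* :func:`build_conditioned_stack` — one normalized ℛ histogram per
  residue type, or per preceding/following neighbor type (the view
  that exposes, e.g., the pre-proline chirality shift).

All products are plain :class:`pandas.DataFrame` objects with labelled
axes, so they serialize to CSV losslessly and can be re-rendered
without touching the source PDB.  Products are built per chain;
pooling across chains must be requested explicitly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import core

__all__ = [
    "build_residue_map",
    "build_histogram_series",
    "build_deviation_map",
    "build_conditioned_stack",
    "histogram_bin_edges",
]


def _select_chain(table: pd.DataFrame, chain: str | None) -> pd.DataFrame:
    chains = list(dict.fromkeys(table["chain"]))
    if chain is None:
        if len(chains) > 1:
            raise ValueError(
                f"table has several chains {chains}; pass chain= or pool explicitly"
            )
        return table
    if chain not in chains:
        raise KeyError(f"chain {chain!r} not in table; available chains: {chains}")
    return table[table["chain"] == chain]


def _ordered_unique(values) -> list:
    return list(dict.fromkeys(values))


def build_residue_map(
    table: pd.DataFrame, chain: str | None = None, signed: bool = False
) -> pd.DataFrame:
    """Residue × frame matrix of ℛ (or ℛₛ with ``signed=True``).

    Rows are residue labels in chain order, columns are model numbers
    in file order; undefined cells (chain termini, breaks) stay NaN so
    they render as gaps rather than shifting the residue axis.
    """
    sub = _select_chain(table, chain)
    value_col = "Rsigned" if signed else "R"
    residues = _ordered_unique(sub["resid"])
    models = _ordered_unique(sub["model"])
    mat = sub.pivot(index="resid", columns="model", values=value_col)
    mat = mat.reindex(index=residues, columns=models)
    mat.index.name = "resid"
    mat.columns.name = "model"
    return mat


def histogram_bin_edges(bin_width: float = 0.01, signed: bool = False) -> np.ndarray:
    """Bin grid over [0, 1] (or [−1, 1] for signed values).

    ``bin_width`` must divide the range evenly.  Bins are half-open
    [lo, hi) except the last, which is closed so that ℛ = 1.0 — a legal
    output, one sweep away from 0 — is counted.
    """
    lo = -1.0 if signed else 0.0
    n = (1.0 - lo) / bin_width
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide the range evenly")
    return np.linspace(lo, 1.0, int(round(n)) + 1)


def _normalized_histogram(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Histogram of defined values, normalized to unit mass (zeros if empty)."""
    defined = values[np.isfinite(values)]
    counts, _ = np.histogram(defined, bins=edges)
    total = counts.sum()
    if total == 0:
        return np.zeros(len(edges) - 1)
    return counts / float(total)


def build_histogram_series(
    table: pd.DataFrame,
    chain: str | None = None,
    bin_width: float = 0.01,
    signed: bool = False,
) -> pd.DataFrame:
    """Per-frame normalized ℛ histograms P′(ℛ), stacked as a matrix.

    Rows are bin centers (ascending), columns are model numbers.  Each
    column sums to 1 over the frame's *defined* ℛ values; a frame with
    none is an all-zero column (flagged with a warning).
    """
    sub = _select_chain(table, chain)
    value_col = "Rsigned" if signed else "R"
    edges = histogram_bin_edges(bin_width, signed=signed)
    centers = 0.5 * (edges[:-1] + edges[1:])
    models = _ordered_unique(sub["model"])
    cols = {}
    for m in models:
        values = sub.loc[sub["model"] == m, value_col].to_numpy(dtype=float)
        col = _normalized_histogram(values, edges)
        if col.sum() == 0:
            warnings.warn(f"model {m}: no defined ℛ values; histogram row is empty")
        cols[m] = col
    out = pd.DataFrame(cols, index=centers)
    out.index.name = "R"
    out.columns.name = "model"
    return out


def build_deviation_map(
    table: pd.DataFrame,
    chain: str | None = None,
    mode: str = "first",
    signed: bool = False,
) -> pd.DataFrame:
    """Residue × frame matrix of structural deviation D₁ or D₋₁.

    ``mode="first"`` compares each frame against the first (D₁),
    ``mode="previous"`` against its predecessor (D₋₁).  A single-model
    input yields an all-zero map (with a warning): there is nothing to
    deviate from.
    """
    if mode not in ("first", "previous"):
        raise ValueError(f"mode must be 'first' or 'previous', got {mode!r}")
    rmap = build_residue_map(table, chain=chain, signed=signed)
    if rmap.shape[1] < 2:
        warnings.warn("deviation map of a single-model input is identically zero")
    fn = core.deviation_from_first if mode == "first" else core.deviation_from_previous
    dev = rmap.apply(lambda row: pd.Series(fn(row.to_numpy()), index=rmap.columns), axis=1)
    dev.index.name = "resid"
    dev.columns.name = "model"
    return dev


def build_conditioned_stack(
    table: pd.DataFrame,
    condition: str = "residue",
    bin_width: float = 0.01,
    signed: bool = False,
) -> pd.DataFrame:
    """Normalized ℛ histogram per residue-type condition, stacked.

    Parameters
    ----------
    condition:
        ``"residue"`` — one row per residue type, the histogram of that
        type's own ℛ values;
        ``"preceding"`` — row Y is the histogram of residues
        immediately *before* a residue of type Y (read N→C), the
        X-before-proline style query;
        ``"following"`` — row Y is the histogram of residues
        immediately *after* type Y.

    Rows with zero members are kept as all-zero rows rather than
    dropped, so sparse conditions stay visible in a stack.  Neighbor
    adjacency never crosses chains or models; pairs spanning a chain
    break contribute nothing because their ℛ values are undefined.
    """
    if condition not in ("residue", "preceding", "following"):
        raise ValueError(
            "condition must be 'residue', 'preceding' or 'following', "
            f"got {condition!r}"
        )
    value_col = "Rsigned" if signed else "R"
    edges = histogram_bin_edges(bin_width, signed=signed)
    centers = 0.5 * (edges[:-1] + edges[1:])
    resnames = sorted(set(table["resname"]))

    groups: dict[str, list[float]] = {name: [] for name in resnames}
    if condition == "residue":
        for name, sub in table.groupby("resname", sort=False):
            groups[name] = sub[value_col].tolist()
    else:
        for (_, _), sub in table.groupby(["model", "chain"], sort=False):
            names = sub["resname"].to_numpy()
            values = sub[value_col].to_numpy(dtype=float)
            if condition == "preceding":
                # value of residue i, conditioned on the type of i+1
                for i in range(len(sub) - 1):
                    groups[names[i + 1]].append(values[i])
            else:
                # value of residue i, conditioned on the type of i-1
                for i in range(1, len(sub)):
                    groups[names[i - 1]].append(values[i])

    rows = {}
    for name in resnames:
        values = np.asarray(groups[name], dtype=float)
        hist = _normalized_histogram(values, edges) if values.size else np.zeros(
            len(centers)
        )
        if hist.sum() == 0:
            warnings.warn(f"condition {name!r}: no defined ℛ values; row is empty")
        rows[name] = hist
    out = pd.DataFrame.from_dict(rows, orient="index", columns=centers)
    out.index.name = "condition"
    out.columns.name = "R"
    return out
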