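"""Synthetic backbone factory and structural metrics.

Builds ideal-geometry polypeptide backbones (N, Cα, C per residue)
from prescribed per-residue (φ, ψ) lists by sequential internal→
Cartesian chain extension (the NeRF construction), writes them as
standard multi-model PDB text, and computes the global shape metrics —
radius of gyration R_g, end-to-end distance R_e and a backbone
chirality proxy χ — whose smooth dependence on ℛ is what makes the
Ramachandran number structurally meaningful.

The bond lengths and angles default to standard ideal protein-backbone
values (Engh–Huber-like); ω is held at 180° (trans).  Sidechains,
sterics and energetics are deliberately out of scope: these chains are
geometric objects for sweeps and test fixtures, not physical models.

The chirality proxy is the mean over consecutive Cα quadruples of the
normalized scalar triple product

    χ_i = (u_i × u_{i+1}) · u_{i+2} / (|u_i × u_{i+1}| |u_{i+2}|)

with u_i the Cα(i)→Cα(i+1) virtual bonds.  It lies in [−1, 1], is zero
for planar chains and changes sign under mirror reflection; its sign
convention (right-handed α-helix → positive) is this module's own and
is pinned only by its tests, not by any external standard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import core
from .structure_io import BackboneChain, BackboneResidue

__all__ = [
    "BackboneGeometry",
    "DEFAULT_GEOMETRY",
    "build_backbone",
    "write_pdb",
    "radius_of_gyration",
    "end_to_end_distance",
    "chirality_proxy",
    "rnumber_binned_trends",
    "make_test_trajectory",
    "disorder_conserved_range",
    "TRAJECTORY_KINDS",
]


@dataclass(frozen=True)
class BackboneGeometry:
    """Ideal backbone internal coordinates (lengths in Å, angles in °)."""

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    angle_n_ca_c: float = 111.0
    angle_ca_c_n: float = 116.6
    angle_c_n_ca: float = 121.9
    omega: float = 180.0

    def __post_init__(self):
        for name in ("bond_n_ca", "bond_ca_c", "bond_c_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("angle_n_ca_c", "angle_ca_c_n", "angle_c_n_ca"):
            a = getattr(self, name)
            if not 0.0 < a < 180.0:
                raise ValueError(f"{name} must lie strictly inside (0, 180)")


DEFAULT_GEOMETRY = BackboneGeometry()


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place the next atom given three predecessors and internal coords.

    ``bond`` is the c–new distance, ``angle_deg`` the b–c–new angle and
    ``torsion_deg`` the a–b–c–new torsion.
    """
    theta = math.radians(angle_deg)
    tau = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(tau),
            bond * math.sin(theta) * math.sin(tau),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(
    dihedrals: Sequence[tuple[float, float]],
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
    chain_id: str = "A",
    resname: str = "GLY",
    start_resid: int = 1,
) -> BackboneChain:
    """Build an ideal backbone realizing the given (φ, ψ) per residue.

    The first residue's φ and the last residue's ψ are geometrically
    unused and may be NaN/None; an undefined dihedral anywhere else is
    an error.  Recomputing torsions from the returned coordinates
    recovers the inputs (up to floating-point noise).
    """
    dihedrals = list(dihedrals)
    if not dihedrals:
        raise ValueError("need at least one residue")

    def _need(value, what, i):
        if value is None or not math.isfinite(value):
            raise ValueError(f"residue {i}: {what} is undefined but required")
        return float(value)

    g = geometry
    coords: list[dict[str, np.ndarray]] = []
    # first residue in a canonical frame: N at origin, CA on +x,
    # C in the xy-plane
    n0 = np.zeros(3)
    ca0 = np.array([g.bond_n_ca, 0.0, 0.0])
    theta = math.radians(g.angle_n_ca_c)
    c0 = ca0 + g.bond_ca_c * np.array([-math.cos(theta), math.sin(theta), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, len(dihedrals)):
        psi_prev = _need(dihedrals[i - 1][1], "psi", i - 1)
        phi_i = _need(dihedrals[i][0], "phi", i)
        prev = coords[-1]
        n_i = _place_atom(
            prev["N"], prev["CA"], prev["C"], g.bond_c_n, g.angle_ca_c_n, psi_prev
        )
        ca_i = _place_atom(
            prev["CA"], prev["C"], n_i, g.bond_n_ca, g.angle_c_n_ca, g.omega
        )
        c_i = _place_atom(prev["C"], n_i, ca_i, g.bond_ca_c, g.angle_n_ca_c, phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})

    chain = BackboneChain(chain_id=chain_id)
    for i, atoms in enumerate(coords):
        chain.residues.append(
            BackboneResidue(
                resid=start_resid + i,
                icode="",
                resname=resname,
                n=atoms["N"],
                ca=atoms["CA"],
                c=atoms["C"],
            )
        )
    return chain


_ELEMENTS = {"N": "N", "CA": "C", "C": "C"}


def write_pdb(models, remark: str | None = None) -> str:
    """Serialize backbone chains as fixed-column PDB text.

    ``models`` is a list of frames; each frame is a
    :class:`BackboneChain` or a list of them.  Multi-frame inputs are
    delimited with MODEL/ENDMDL; a single frame is written bare.
    Coordinates round-trip through :func:`ramamap.structure_io.parse_pdb`
    to 3 decimals.
    """
    models = list(models)
    if not models:
        raise ValueError("no models to write")
    frames = [
        [frame] if isinstance(frame, BackboneChain) else list(frame)
        for frame in models
    ]
    lines: list[str] = []
    if remark:
        lines.append(f"REMARK   1 {remark}")
    multi = len(frames) > 1
    for frame_idx, chains in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {frame_idx:4d}")
        serial = 1
        for chain in chains:
            for res in chain.residues:
                for atom_name in ("N", "CA", "C"):
                    pos = res.atom(atom_name)
                    if pos is None:
                        continue
                    name_field = (" " + atom_name).ljust(4)  # cols 13-16
                    lines.append(
                        f"ATOM  {serial:5d} {name_field} {res.resname:>3s} "
                        f"{chain.chain_id:1s}{res.resid:4d}{res.icode[:1] or ' '}   "
                        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          "
                        f"{_ELEMENTS[atom_name]:>2s}"
                    )
                    serial += 1
            lines.append(f"TER   {serial:5d}")
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _backbone_coords(chain: BackboneChain) -> np.ndarray:
    pts = []
    for res in chain.residues:
        for name in ("N", "CA", "C"):
            p = res.atom(name)
            if p is not None:
                pts.append(p)
    return np.asarray(pts, dtype=float)


def radius_of_gyration(chain: BackboneChain) -> float:
    """Root-mean-square distance of backbone atoms from their centroid (Å)."""
    pts = _backbone_coords(chain)
    if pts.size == 0:
        raise ValueError("chain has no atoms")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def end_to_end_distance(chain: BackboneChain) -> float:
    """Distance from the first residue's N to the last residue's C (Å)."""
    pts = _backbone_coords(chain)
    if len(pts) < 2:
        raise ValueError("need at least two atoms")
    first_n = chain.residues[0].n
    last_c = chain.residues[-1].c
    if first_n is None or last_c is None:
        raise ValueError("terminal N/C atoms missing")
    return float(np.linalg.norm(last_c - first_n))


def chirality_proxy(chain: BackboneChain) -> float:
    """Mean normalized Cα triple product, in [−1, 1]; NaN below 4 Cα."""
    cas = np.asarray(
        [res.ca for res in chain.residues if res.ca is not None], dtype=float
    )
    if len(cas) < 4:
        return float("nan")
    u = np.diff(cas, axis=0)
    vals = []
    for i in range(len(u) - 2):
        cr = np.cross(u[i], u[i + 1])
        denom = np.linalg.norm(cr) * np.linalg.norm(u[i + 2])
        if denom < 1e-12:
            vals.append(0.0)
        else:
            vals.append(float(np.dot(cr, u[i + 2]) / denom))
    return float(np.mean(vals))


def rnumber_binned_trends(
    step: float = 5.0,
    bin_width: float = 0.01,
    n_res: int = 10,
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Sweep uniform-(φ, ψ) chains over the full grid and bin shape
    metrics by ℛ.

    For every (φ, ψ) on the inclusive grid [−180, −180+step, …, 180]²
    a homopolymer of ``n_res`` residues is built with that dihedral
    pair at every position, its R_g, R_e and χ computed, and the
    results binned by ℛ(φ, ψ) into bins of ``bin_width``.

    Returns
    -------
    pandas.DataFrame
        One row per non-empty bin: ``bin_center, count`` and
        ``{rg,re,chi}_{mean,sd}``.
    """
    if not (step > 0 and math.isclose((360.0 / step) % 1.0, 0.0, abs_tol=1e-9)):
        raise ValueError("step must evenly divide 360")
    grid = np.arange(-180.0, 180.0 + 0.5 * step, step)
    records = []
    for phi in grid:
        for psi in grid:
            chain = build_backbone(
                [(phi, psi)] * n_res, geometry=geometry
            )
            records.append(
                (
                    core.ramachandran_number(phi, psi),
                    radius_of_gyration(chain),
                    end_to_end_distance(chain),
                    chirality_proxy(chain),
                )
            )
    df = pd.DataFrame(records, columns=["R", "rg", "re", "chi"])
    n_bins = int(round(1.0 / bin_width))
    idx = np.minimum((df["R"] / bin_width).astype(int), n_bins - 1)
    df["bin_center"] = (idx + 0.5) * bin_width
    grouped = df.groupby("bin_center")
    out = grouped.agg(
        count=("R", "size"),
        rg_mean=("rg", "mean"),
        rg_sd=("rg", "std"),
        re_mean=("re", "mean"),
        re_sd=("re", "std"),
        chi_mean=("chi", "mean"),
        chi_sd=("chi", "std"),
    ).reset_index()
    return out


# canonical (φ, ψ) loci used by the fixture trajectories
_HELIX = (-57.0, -47.0)
_SHEET = (-120.0, 135.0)
# extended locus kept off the ±180° wrap edge so jitter stays in one band
_EXTENDED = (-160.0, 160.0)  # extended, ℛ = 0.5
_BAND_LOW = (-80.0, -60.0)  # ℛ ≈ 0.31
_BAND_HIGH = (75.0, 85.0)  # ℛ ≈ 0.72

TRAJECTORY_KINDS = ("stable-helix", "disorder", "helix-to-sheet", "restrained-release")


def disorder_conserved_range(n_res: int) -> range:
    """Residue indices (0-based) of the conserved helical segment in the
    ``disorder`` trajectory: the middle third of the chain."""
    start = n_res // 3
    return range(start, min(n_res, start + max(3, n_res // 3)))


def make_test_trajectory(
    kind: str,
    n_res: int = 20,
    n_frames: int = 20,
    seed: int = 0,
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
) -> str:
    """Deterministic multi-model PDB text emulating archetypal dynamics.

    Kinds
    -----
    ``stable-helix``
        Every residue jitters (σ = 5°) about the α-helical basin
        (−57°, −47°) in every frame: a conformationally stable protein.
    ``disorder``
        Residues resample broadly over the plot each frame, except one
        conserved helical segment (the middle third) that stays put
        with small (σ = 2°) jitter — the intrinsically-disordered-with-
        one-stable-helix pattern.
    ``helix-to-sheet``
        All residues interpolate from the helical to the sheet basin
        over the frames, with small jitter: a cooperative transition.
    ``restrained-release``
        The first third of the frames holds every residue fully
        extended (ℛ ≈ 0.5); afterwards even residues settle near
        ℛ ≈ 0.31 and odd residues near ℛ ≈ 0.72, producing the birth
        of a bimodal two-band histogram.

    Same ``seed`` ⇒ byte-identical output.
    """
    if kind not in TRAJECTORY_KINDS:
        raise ValueError(f"unknown kind {kind!r}; choose from {TRAJECTORY_KINDS}")
    if n_res < 3 or n_frames < 1:
        raise ValueError("need n_res >= 3 and n_frames >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    conserved = disorder_conserved_range(n_res)
    for t in range(n_frames):
        dihedrals = []
        for i in range(n_res):
            if kind == "stable-helix":
                phi, psi = rng.normal(_HELIX, 5.0)
            elif kind == "disorder":
                if i in conserved:
                    phi, psi = rng.normal(_HELIX, 2.0)
                else:
                    phi, psi = rng.uniform(-180.0, 180.0, size=2)
            elif kind == "helix-to-sheet":
                frac = t / max(1, n_frames - 1)
                target = (
                    _HELIX[0] + frac * (_SHEET[0] - _HELIX[0]),
                    _HELIX[1] + frac * (_SHEET[1] - _HELIX[1]),
                )
                phi, psi = rng.normal(target, 3.0)
            else:  # restrained-release
                if t < max(1, n_frames // 3):
                    phi, psi = rng.normal(_EXTENDED, 4.0)
                else:
                    target = _BAND_LOW if i % 2 == 0 else _BAND_HIGH
                    phi, psi = rng.normal(target, 4.0)
            dihedrals.append((float(phi), float(psi)))
        frames.append(build_backbone(dihedrals, geometry=geometry))
    return write_pdb(frames)
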