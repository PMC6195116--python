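"""Multi-model PDB ingestion and backbone dihedral extraction.

Reads standard PDB files — a single structure, or an ensemble /
trajectory whose frames are delimited by MODEL records — keeps only the
backbone atoms N, Cα, C, computes per-residue (φ, ψ) from coordinates
and emits one flat table with the derived Ramachandran numbers.

Parsing is delegated to :mod:`gemmi`; this module adds the backbone
reduction, alternate-location resolution (highest occupancy wins, ties
to the first conformer in the file), chain-break detection and the
table schema consumed by :mod:`ramamap.maps`.

Conventions recorded here because the field has no single one:

* terminal residues keep their rows with NaN φ (first) / ψ (last) so
  the residue axis stays aligned across models;
* a C(i−1)–N(i) distance above ``break_cutoff`` (default 2.0 Å; the
  peptide bond is ≈ 1.33 Å) is a chain break: φ_i and ψ_{i−1} are
  undefined across it;
* MODEL serial numbers are used verbatim as frame labels, gaps and all;
* residues with insertion codes keep them in the ``resid`` label,
  ordered after their base number as they appear in the file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from . import core

__all__ = [
    "BackboneResidue",
    "BackboneChain",
    "parse_pdb",
    "dihedral_angle",
    "compute_dihedrals",
    "read_pdb",
    "TABLE_COLUMNS",
]

BACKBONE_ATOMS = ("N", "CA", "C")
DEFAULT_BREAK_CUTOFF = 2.0  # Å; peptide C–N bond is ~1.33 Å

TABLE_COLUMNS = ["model", "chain", "resid", "resname", "phi", "psi", "R", "Rsigned"]


@dataclass
class BackboneResidue:
    """One residue's backbone: coordinates of N, Cα and C (or None)."""

    resid: int
    icode: str
    resname: str
    n: np.ndarray | None = None
    ca: np.ndarray | None = None
    c: np.ndarray | None = None

    @property
    def label(self) -> str | int:
        """Residue label: plain number, or number+insertion code."""
        return f"{self.resid}{self.icode}" if self.icode.strip() else self.resid

    def atom(self, name: str) -> np.ndarray | None:
        return {"N": self.n, "CA": self.ca, "C": self.c}[name]


@dataclass
class BackboneChain:
    """Ordered backbone of one chain in one model."""

    chain_id: str
    residues: list[BackboneResidue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> gemmi.Atom | None:
    """Resolve alternate locations: highest occupancy, ties to first."""
    best = None
    for atom in atoms:
        if best is None or atom.occ > best.occ + 1e-9:
            best = atom
    return best


def parse_pdb(source: str | Path) -> list[tuple[int, list[BackboneChain]]]:
    """Parse PDB text or a file path into backbone models.

    Parameters
    ----------
    source:
        Path to a PDB file, or the PDB text itself (anything containing
        a newline is treated as text).

    Returns
    -------
    list of (model_number, chains)
        One entry per MODEL record; a file without MODEL records yields
        a single model numbered 1.  Only N/CA/C atoms of polymer
        residues are retained.

    Raises
    ------
    ValueError
        If the input contains no ATOM records or cannot be parsed.
    """
    try:
        if isinstance(source, Path) or "\n" not in str(source):
            structure = gemmi.read_pdb(str(source))
        else:
            structure = gemmi.read_pdb_string(str(source))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB input: {exc}") from exc

    models: list[tuple[int, list[BackboneChain]]] = []
    for model in structure:
        chains = []
        for chain in model:
            bb = BackboneChain(chain_id=chain.name)
            for res in chain:
                # HETATM entries (waters, ligands) are skipped unless the
                # residue actually carries a protein backbone.
                by_name: dict[str, list[gemmi.Atom]] = {}
                for atom in res:
                    if atom.name in BACKBONE_ATOMS:
                        by_name.setdefault(atom.name, []).append(atom)
                if not by_name:
                    continue
                rec = BackboneResidue(
                    resid=res.seqid.num, icode=res.seqid.icode, resname=res.name
                )
                for name, atoms in by_name.items():
                    atom = _pick_altloc(atoms)
                    pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    setattr(rec, name.lower() if name != "CA" else "ca", pos)
                bb.residues.append(rec)
            if len(bb):
                chains.append(bb)
        if chains:
            models.append((model.num, chains))
    if not models:
        raise ValueError("no ATOM records with backbone atoms found")
    return models


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, IUPAC sign convention, in [−180, 180).

    Returns NaN when the geometry is degenerate (zero-length bond or
    collinear consecutive triple).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2_norm = np.linalg.norm(b2)
    if b2_norm < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        return float("nan")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / b2_norm
    angle = math.degrees(math.atan2(y, x))
    if angle >= 180.0:
        angle -= 360.0
    return angle


def _residue_dihedrals(
    chain: BackboneChain, break_cutoff: float
) -> list[tuple[float, float]]:
    """Per-residue (φ, ψ) for one chain; NaN where undefined."""
    res = chain.residues
    n = len(res)
    # linkage[i] is True when the peptide bond C(i) – N(i+1) is intact
    linkage = []
    for i in range(n - 1):
        c_prev, n_next = res[i].c, res[i + 1].n
        ok = (
            c_prev is not None
            and n_next is not None
            and np.linalg.norm(n_next - c_prev) <= break_cutoff
        )
        linkage.append(ok)

    out = []
    nan = float("nan")
    for i in range(n):
        phi = nan
        psi = nan
        r = res[i]
        complete = r.n is not None and r.ca is not None and r.c is not None
        if i > 0 and linkage[i - 1] and complete and res[i - 1].c is not None:
            phi = dihedral_angle(res[i - 1].c, r.n, r.ca, r.c)
        if i < n - 1 and linkage[i] and complete and res[i + 1].n is not None:
            psi = dihedral_angle(r.n, r.ca, r.c, res[i + 1].n)
        out.append((phi, psi))
    return out


def compute_dihedrals(
    models: Sequence[tuple[int, list[BackboneChain]]],
    break_cutoff: float = DEFAULT_BREAK_CUTOFF,
) -> pd.DataFrame:
    """Build the per-residue dihedral table from parsed models.

    φ_i is the torsion C(i−1)–N(i)–Cα(i)–C(i); ψ_i is
    N(i)–Cα(i)–C(i)–N(i+1).  The first residue of a chain (or of a
    segment after a break) has no φ; the last has no ψ.  ℛ and ℛₛ are
    defined only where both dihedrals are.

    Returns
    -------
    pandas.DataFrame
        Columns ``model, chain, resid, resname, phi, psi, R, Rsigned``;
        one row per residue per model, in file order.
    """
    rows = []
    for model_num, chains in models:
        for chain in chains:
            dihedrals = _residue_dihedrals(chain, break_cutoff)
            for res, (phi, psi) in zip(chain.residues, dihedrals):
                rows.append((model_num, chain.chain_id, res.label, res.resname, phi, psi))
    df = pd.DataFrame(rows, columns=["model", "chain", "resid", "resname", "phi", "psi"])
    df["R"] = core.ramachandran_number(df["phi"].to_numpy(), df["psi"].to_numpy())
    df["Rsigned"] = core.signed_ramachandran_number(
        df["phi"].to_numpy(), df["psi"].to_numpy()
    )
    return df


def read_pdb(
    source: str | Path, break_cutoff: float = DEFAULT_BREAK_CUTOFF
) -> pd.DataFrame:
    """One-call convenience: parse a PDB and return the dihedral table."""
    return compute_dihedrals(parse_pdb(source), break_cutoff=break_cutoff)
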