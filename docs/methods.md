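# Methods

## The Ramachandran number

The backbone conformation of residue *i* in a protein or peptoid is
dominated by its two dihedral angles (φᵢ, ψᵢ).  The Ramachandran number
collapses this pair into one scalar by sweeping the Ramachandran plot
along lines parallel to the negatively sloping diagonal:

    ℛ(φ, ψ) = (φ + ψ − (φ_min + ψ_min)) / ((φ_max + ψ_max) − (φ_min + ψ_min))

With the default convention φ, ψ ∈ [−180°, 180°) this reduces to
ℛ = (φ + ψ + 360°)/720° ∈ [0, 1].  ℛ depends only on φ + ψ; it is
constant along each diagonal sweep and strictly increasing across them.
The collapse is informative because the dominant secondary structures
occupy distinct sweeps: right-handed α-helices near ℛ ≈ 0.34 (the
canonical (−57°, −47°) basin maps to ℛ = 0.356), β-strands near
ℛ ≈ 0.52, polyproline-II helices near ℛ ≈ 0.60, and extended states
near ℛ ∈ {0, 0.5, 1}.  Global shape metrics (radius of gyration,
end-to-end distance, handedness) vary far more across sweeps than
along them, which is what licenses the dimensionality reduction.

Conventions adopted here:

* **Wrapping.** Inputs outside the bounds are wrapped by multiples of
  360°.  Values exactly on the closed upper edge keep their face value,
  so ℛ(180°, 180°) = 1.0 rather than 0.0; the two labels denote the
  same conformation one full sweep apart, and retaining 1.0 keeps the
  upper corner distinguishable in maps.
* **Undefined dihedrals** (chain termini, breaks, missing atoms)
  propagate as NaN end to end rather than being dropped, so residue
  axes stay aligned across frames.
* **Units.** Degrees internally; radian bounds are accepted through
  `AngleBounds.from_radians`.

## Signed ℛ

Most chiral backbones occupy the upper-left half-plane ψ ≥ φ.  Achiral
backbones (glycine-rich peptides, peptoids) occupy both halves, and
two distinct structures on the same sweep — e.g. ppII and the
mirror-image α_D helix — then share one ℛ.  The signed variant

    ℛₛ = ℛ if ψ ≥ φ, else −ℛ

separates them.  The boundary ψ = φ is assigned to the positive
branch, so ℛₛ(0, 0) = +0.5.

## The σ-discretized oracle

The original formulation tiles the plot into squares of side 1/σ and
indexes them with integers that increase along diagonal sweeps:

    R_ℤ(φ, ψ) = [(φ − ψ + λ)σ/√2] + [√2 λ σ]·[(φ + ψ + λ)σ/√2]

with λ = 360° and [x] nearest-integer rounding, normalized between the
two corners of the bounds.  As σ → ∞ this converges to the closed form
above; the implementation keeps it as an independent numerical oracle.
Nearest-integer half-ties are rounded away from zero — the convergence
behaviour is insensitive to the tie rule, so the simplest consistent
one is used.  Measured on a 1° grid, the maximum deviation from the
closed form falls monotonically from 1.9 × 10⁻³ at σ = 1 to
1.9 × 10⁻⁶ at σ = 1000.

## Dihedrals from coordinates

φᵢ is the torsion C(i−1)–N(i)–Cα(i)–C(i) and ψᵢ the torsion
N(i)–Cα(i)–C(i)–N(i+1), computed with the standard atan2 form under
the IUPAC sign convention and wrapped to [−180°, 180°).  Degenerate
geometry (zero-length bonds, collinear triples) yields NaN.  Policies
the source format leaves open:

* alternate locations: the highest-occupancy conformer wins, ties to
  the first in file;
* chain breaks: a C(i−1)–N(i) distance above 2.0 Å (peptide bond
  ≈ 1.33 Å) severs φᵢ and ψ(i−1);
* MODEL serial numbers label frames verbatim, gaps included;
* insertion-coded residues keep the code in their label, in file
  order.

## MAP products

Per chain (never pooled across chains unless requested):

* **Residue map** — residue × frame matrix of ℛ (or ℛₛ).
* **Histogram series** — per-frame normalized histograms P′(ℛ) over
  100 bins of width 0.01 by default; bins are half-open [lo, hi) with
  the final bin closed so ℛ = 1.0 is counted; normalization is over
  defined observations only, and per frame (each column sums to 1).
* **Deviation maps** — D₁ = |ℛ_t − ℛ₁| (drift from the starting
  structure) and D₋₁ = |ℛ_t − ℛ_{t−1}| (frame-to-frame flicker); the
  first frame is 0 by definition.
* **Conditioned stacks** — one normalized ℛ histogram per residue
  type, or per neighbor type read N→C (residues *before* type Y /
  *after* type Y).  Empty conditions are kept as flagged zero rows so
  sparse residue types remain visible when stacked.

## Color schemes

Qualitative keys, anchored at the secondary-structure loci:
`Chirality` is a diverging red–white–blue map centered on ℛ = 0.5
(right-twisting red, left-twisting blue, exactly neutral at the
midpoint); `SecondaryStructure` places red at 0.34 (helix), blue at
0.52 (sheet) and cyan at 0.60 (ppII) on a white field.  Exact anchor
RGBs are configuration, not science, and can be overridden per
`ColorScheme`.  `colormap_value` interpolates the anchors directly so
the anchor colors are exact; images use the equivalent matplotlib
colormap.

## Synthetic backbones

Chains are grown atom by atom from internal coordinates (the natural
extension reference frame construction) with ideal geometry: bonds
N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; angles N–Cα–C 111.0°,
Cα–C–N 116.6°, C–N–Cα 121.9°; ω fixed at 180°.  These are standard
ideal values, exposed through `BackboneGeometry`.  The construction is
validated two ways: recomputing torsions from the built coordinates
recovers the prescribed (φ, ψ) (round trips through PDB text stay
within 0.5°, limited by the format's 3-decimal coordinates), and the
(−57°, −47°) chain reproduces textbook α-helix parameters (rise
1.56 Å/residue, Cα radius 2.27 Å, 3.6 residues/turn).

Shape metrics on a built chain: R_g is the RMS distance of backbone
atoms from their centroid; R_e is the first-N-to-last-C distance; the
chirality proxy χ is the mean over consecutive Cα quadruples of the
normalized scalar triple product (u_i × u_{i+1})·u_{i+2} /
(|u_i × u_{i+1}||u_{i+2}|) of the virtual Cα–Cα bonds.  χ ∈ [−1, 1],
vanishes for planar chains and is antisymmetric under mirror
reflection; its sign convention (right-handed α-helix positive) is
internal to this package.  It is a geometric stand-in for
twist-handedness order parameters defined elsewhere; only signs and
orderings are asserted against it, never magnitudes.

The sweep `rnumber_binned_trends` builds a length-10 homopolymer for
every (φ, ψ) on the inclusive 5° grid (73² = 5329 chains by default),
bins the metrics by ℛ in 0.01-wide bins, and reports per-bin means and
SDs.  On this sweep R_e peaks at the ℛ extremes and χ is
mirror-antisymmetric about ℛ = 0.5 (positive on the right-handed side
below 0.5).  One finding worth flagging: the binned R_g minimum falls
at ℛ ≈ 0.275, the near-zero-rise "ring" conformation at
φ + ψ ≈ −152°, slightly below the α-helical band at 0.34–0.36.  The
α-helix is near, but not at, the most compact uniform geometry once
every sweep is populated uniformly; sterically weighted ensembles
would pull the minimum toward the helical band.

## Fixture trajectories

`make_test_trajectory` emits deterministic multi-model PDB text for
four archetypes (seeded `numpy` generator; identical seed ⇒ identical
bytes):

* `stable-helix` — all residues jitter (σ = 5°) about (−57°, −47°);
* `disorder` — broad uniform resampling every frame except a conserved
  middle-third helical segment (σ = 2°), the
  disordered-protein-with-one-stable-helix signature;
* `helix-to-sheet` — linear interpolation of the basin from
  (−57°, −47°) to (−120°, 135°) with σ = 3° jitter;
* `restrained-release` — the first third of the frames holds an
  extended ℛ ≈ 0.5 band at (−160°, 160°), after which alternating
  residues settle near ℛ ≈ 0.31 and ℛ ≈ 0.72: a single band splitting
  into two parallel bands.  The extended locus is kept off the ±180°
  wrap edge deliberately: the edge is a representation artifact, and
  jitter across it would split one physical band into two display
  bands.

What these fixtures emulate is the *ℛ-space signature* of the
corresponding dynamics — band positions, band counts, per-residue
stability — not the physics that produces it: there is no energy
model, no sterics, no correlation between neighboring residues or
consecutive frames beyond what the archetype prescribes.  Tests
passing on them demonstrate that the analysis pipeline detects such
signatures when present; they say nothing about whether real
trajectories contain them.

## Problem sizes and numerics

Default analysis sizes (fixture trajectories of 15–30 residues ×
15–20 frames, 500-conformation round-trip checks, the full 5° sweep)
were chosen as the smallest sizes at which the qualitative signatures
are unambiguous; all complete in seconds on one CPU.  Angle
comparisons in round-trip checks are circular (mod 360°, and mod 1 for
ℛ), since a value within coordinate-rounding noise of ±180° may be
recovered as its wrapped representative.  Histogram mass conservation
is exact to 1 × 10⁻⁹; dihedral recovery through PDB text is limited to
≈ 0.1° by the format's fixed 3-decimal coordinate columns.

## Known limitations

* No secondary-structure *classification* is performed; the ℛ loci are
  descriptive bands, not hard thresholds.
* ω is fixed in generated structures and ignored in analysis; cis
  peptide bonds in input structures are simply reflected in whatever
  φ/ψ they produce.
* The chirality proxy is not the literature's twist order parameter;
  only its sign structure is meaningful here.
* Multi-character (mmCIF) chain IDs, sidechains and trajectory formats
  other than multi-model PDB are out of scope.
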