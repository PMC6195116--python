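# ramamap

Compact per-residue description of protein and peptoid backbone
conformation with the **Ramachandran number**, and stacked "multi-angle
picture" (MAP) graphics for ensembles and trajectories.

## The problem

A residue's backbone conformation lives in the two-dimensional
Ramachandran plane (φ, ψ).  That is fine for one structure, but an NMR
ensemble or a simulation trajectory multiplies every residue into a
curve in that plane, and picking out transitions, disorder, or one
conserved segment among hundreds of frames becomes impractical.  The
Ramachandran number collapses the pair into a single scalar

    ℛ(φ, ψ) = (φ + ψ + 360°) / 720°   ∈ [0, 1]

taken along the negatively sloping diagonal sweeps of the plot, with
little loss of structural information: α-helices sit near ℛ ≈ 0.34,
β-strands near ℛ ≈ 0.52, polyproline-II helices near ℛ ≈ 0.6, and
ℛ < 0.5 / ℛ > 0.5 separates right- from left-twisting backbones.  A
whole structure becomes a one-dimensional "ℛ-code" — a per-residue
string or a histogram — and ℛ-codes from many frames stack side by
side into a single matrix picture of the whole trajectory.  For
achiral backbones (polyglycines, peptoids) the signed variant
ℛₛ = ±ℛ (negative when ψ < φ) resolves mirror-image ambiguities.

Intended users: anyone staring at multi-model PDB files — NMR
ensembles, MD snapshots, design pipelines — who wants residue-level,
hypothesis-free pictures of what the backbone is doing.

## Worked example

```python
>>> import ramamap
>>> ramamap.ramachandran_number(0, 0)
0.5
>>> ramamap.ramachandran_number(-57, -47)   # alpha-helix
0.35555555555555557
>>> ramamap.ramachandran_number(-120, 135)  # beta-strand
0.5208333333333334
>>> ramamap.signed_ramachandran_number(145, -75)  # mirror of ppII
-0.5972222222222222
```

The helical basin lands in the ℛ ≈ 0.34–0.36 band, the β-strand at
0.52, and the mirror image of a ppII helix keeps the ppII magnitude
(0.597) with a negative sign — same sweep, opposite handedness.

End-to-end, on a synthetic trajectory that mimics a restrained
extended backbone relaxing into an alternating-chirality state:

```sh
ramamap fixtures --kind restrained-release --n-res 24 --frames 15 \
        --seed 3 --out nanoribbon.pdb
ramamap --pdb nanoribbon.pdb --out maps_out
```

writes, for chain A, five panels (PNG + CSV sidecar each): the
per-frame ℛ histogram series, per-residue maps in the Chirality and
SecondaryStructure color schemes, and the two deviation maps D₁
(drift from frame 1) and D₋₁ (frame-to-frame change).  Reading the
histogram sidecar back:

```text
frame 1  mass in R [0.40,0.60): 1.0
frame 15 mass in R [0.25,0.37): 0.5
frame 15 mass in R [0.66,0.78): 0.5
```

i.e. the first frame is a single extended band at ℛ ≈ 0.5, and by the
last frame the distribution has split into two parallel bands — half
the residues near ℛ ≈ 0.31, half near ℛ ≈ 0.72 — the bimodal
signature of the relaxed state, visible at a glance in the histogram
MAP.

Library surface: `ramamap.read_pdb` → tidy per-residue table
(`model, chain, resid, resname, phi, psi, R, Rsigned`);
`ramamap.maps.build_residue_map / build_histogram_series /
build_deviation_map / build_conditioned_stack` → labelled DataFrames;
`ramamap.render.draw_map` → images; `ramamap.structgen` → ideal-
geometry backbone construction, shape-metric sweeps and fixture
trajectories.  See `docs/methods.md` for conventions and assumptions.

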