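# Methods

## Scope and data model

`oligoraft` analyses particle trajectories of protein/membrane systems; it
does not simulate dynamics. A `System` carries per-atom annotations
(molecule id and type, force-field type key, protein chain and 1-based
residue index) plus reference coordinates; a `Trajectory` is an ordered
list of frames over one system. Internal units are nm for length and
kJ/mol for energy (PDB Å are converted on read); frame times are in the
natural unit of the resolution tag — microseconds for coarse-grained (CG)
runs, nanoseconds for all-atom (AA) runs. Boxes are orthorhombic; triclinic
input is rejected so the minimum-image search stays exact. Periodicity is
applied laterally (x, y) only: the bilayer normal is the z axis, and
treating z as aperiodic keeps leaflet assignment and tilt angles
unambiguous for a planar membrane. Residue indices are 1-based and
intervals inclusive throughout, matching how residue-resolved plots are
conventionally labelled.

## Domain classification

A DPPC with any atom within the proximity threshold d_domain (default
0.5 nm, inclusive) of any DLPC atom is labelled Lod, otherwise Lo;
symmetrically DLPC is Lod or Ld. The threshold comparison is inclusive by
convention. Cholesterol contacting PCs of exactly one phase class inherits
that class; contacting two or more classes it is labelled Lod (a molecule
touching both phases sits at the boundary, which is what Lod means);
contacting none, it takes the class of the nearest PC molecule.
Classification uses 3D distances jointly over both leaflets with no leaflet
pre-filter — inter-leaflet contacts are excluded geometrically by bilayer
thickness, not by bookkeeping. The neighbour search is a laterally periodic
k-d tree validated against an exhaustive O(N²) nine-image oracle in the
test suite.

Compositions: the CHOL triple is per-domain counts over total CHOL × 100;
the PC triple is (Lo-DPPC, Ld-DLPC, Lod-PC) over total DPPC+DLPC × 100,
where Lod-PC pools boundary DPPC and DLPC. Each triple sums to 100 by
construction. Percentages are time-averaged per replicate, then averaged
across replicates; the SEM is across replicates (ddof = 1, absent for a
single replicate). The default analysis window is the last 5 µs of a CG
run / last 50 ns of an AA run, i.e. the equilibrated tail.

## Binding analysis

*mindist* is the minimum over all cross-group atom pairs of the
minimum-image distance; all protein atoms enter, not only the backbone.
Contact counts are the number of cross pairs within d_contact, default
2.0 nm — deliberately large, kept configurable. Binding-time detection
offers two rules. The primary `persistent_suffix` rule returns the earliest
frame from which the mindist stays at or below d_bind through the end of
the trajectory, reflecting the firmly-attached phenomenology the pipeline
targets; an optional dwell-window variant (earliest frame followed by k
bound frames) is exposed for transiently bound cases. The `contact_onset`
rule returns the first frame of the trailing run of nonzero contacts. The
default d_bind of 0.6 nm (CG) sits above the ~0.5 nm CG plateau plus twice
the generator's noise scale, so both detectors agree to within one frame
spacing on synthetic data; 0.35 nm is the analogous AA choice above a
~0.2 nm plateau.

The mindist spectrum resolves the per-frame minimum per protein residue,
averages over the window frames, then over equivalent chains of one
monomer type (which must share a sequence length), then across replicates
with SEM. A centred 5-point moving average (windows truncated at the
termini, never padded) is attached for presentation only; the unsmoothed
values are always retained.

Annular lipids (AL): a lipid belongs to the shell iff any of its atoms is
within d_shell (default 0.5 nm) of any protein atom; nAL is the complement.
Per-type AL percentages are reported as absent when the shell is empty
rather than as 0/0.

## Chain order profiles

The reported order parameter is the second-Legendre average of the local
chain-axis tilt: for interior carbon n the axis is position(n+1) −
position(n−1) and S(n) = ⟨(3cos²θₙ − 1)/2⟩ against the z axis. This is the
molecular-axis (three-consecutive-carbon) construction, **not** the
deuterium order parameter S_CD — the two differ in sign and scale, so the
convention is stated prominently. Angles are folded into [0, π/2] (P₂ is
insensitive to axis sign); S is bounded in [−0.5, 1] and defined for
carbons 2…N−1 only. The bilayer normal is fixed to z per frame (no local
normal estimation; the fixtures are planar). Double-bond carbons receive no
special treatment. Shell filters (AL/nAL) are re-evaluated per frame, and
the molecule-weighted AL + nAL average recomposes the unfiltered profile
exactly on each frame — an identity the tests assert.

## Nonbonded energetics

Pair energies are the standard 12-6 Lennard-Jones
4ε[(σ/r)¹² − (σ/r)⁶] and vacuum Coulomb f·qᵢqⱼ/r with
f = 1/(4πε₀) = 138.935458 kJ·mol⁻¹·nm·e⁻² (CODATA-derived, overridable).
Group energies sum all cross pairs within a plain truncation cutoff
(default 1.2 nm) under Lorentz–Berthelot combining (arithmetic σ, geometric
ε) — the dominant convention for the atomistic force fields this mirrors.
No shift/switch, no long-range corrections, no reaction field or PME: the
outputs are raw interaction energies, not free energies, and truncation
makes them discontinuous but deterministic functions of the positions
(continuity is documented as absent, not asserted). Interchain energy sums
over all unordered distinct chain pairs and is reported as not-applicable
for monomers. Only cross-group pairs are summed; no intramolecular
exclusion rules are applied because no intra-group pairs are evaluated.

## Protein structure

Hydropathy uses the Kyte–Doolittle scale with the same truncated centred
moving average (default window 5). DSSP one-letter codes are an input —
produced externally or by the synthetic generator; the DSSP algorithm
itself is out of scope. Regrouping: beta ← {E, B}, alpha ← {H, G, I},
turn ← {T}, random ← {S, C, blank}; blank codes are treated as coil (the
standard DSSP output convention), and per-frame category counts always
partition the residue total. Summaries support residue subsets (extracting
the constituent chains of a hetero-oligomer) and stacked sums (comparing a
hetero-oligomer against the concatenation of the corresponding
homo-oligomers, which match in total residue count: 167 for the dimer
comparison, 334 for the tetramer comparison).

Contact maps hold the time-mean and the population standard deviation of
residue–residue minimum atom distances over the window. The diagonal and
sequence-adjacent pairs are included (no exclusions); consumers may mask.
The interface block restricted to two distinct chains is the
residue-resolved cross-chain map; requesting a self-interface is an error.

## Protein sequences

Two monomers are packaged: human amylin (islet amyloid polypeptide,
37 residues) and a 130-residue tau construct — the four-repeat
microtubule-binding fragment (K18; tau 244–372 in 2N4R numbering) with an
initiator methionine. The choice of fragment is fixed by its hydrophobic
landmarks: V6, I35, I66, I86, I112 and V121 in construct numbering all
fall at the K18 repeat positions, and amylin's C7, L16, I26 and V32 are
likewise verified against the canonical sequence. Hetero-oligomers are the
tau–amylin dimer `1tam` (chains tau, amylin; 167 residues) and tetramer
`2tam` (chains amylin, tau, tau, amylin; 334 residues).

## Synthetic generator

The generator emulates the study conditions so every analysis can be
closed against planted ground truth; it performs no physical dynamics.

*Raft geometry.* Each leaflet is a square lattice at 0.64 nm² per lipid.
Sites are assigned inside-out from the box centre: the anionic cluster
(POPS or GM1) innermost, then DPPC and CHOL interleaved through the Lo
disc, then DLPC outside, with an optional radial gap isolating the phases
for zero-boundary-mixing fixtures. Full-scale compositions are the
standard PS-raft (162 POPS / 666 DPPC / 540 DLPC / 576 CHOL) and GM-raft
(36 GM1 / 709 DPPC / 407 DLPC / 410 CHOL); the per-leaflet split is not
specified anywhere, so non-anionic species split evenly (odd molecule to
the upper leaflet) and the anionic species occupies the upper leaflet only
— asymmetry is preserved by construction, never by dynamics. Tests default
to ~1/8-scale compositions for desk-scale runtimes; the scale factor is a
flag. Lipids are bead chains: one headgroup reference bead plus 4 chain
beads per acyl chain (3 for the CHOL ring stack) at 0.25 nm spacing.
Head planes sit at max-chain-extension + 0.3 nm from the midplane, which
guarantees an inter-leaflet gap > 0.5 nm so cross-leaflet contacts can
never contaminate domain labels; anionic headgroups protrude 0.3 nm above
the PC surface (GM1's bulky carbohydrate head, PS's extended headgroup),
which also makes the cluster the protein's first contact. Chain tilts are
drawn per chain from a two-component mixture — perfectly aligned (or
in-plane, for negative targets) with the weight that fixes ⟨P₂⟩, plus an
isotropic component — so the planted order parameter is exact in
expectation and degenerate targets (S = 1, S = −0.5) are exact pointwise.
Default planted order: 0.85 for the ordered species (DPPC, CHOL, POPS,
GM1), 0.45 for DLPC.

*Binding trajectories.* The oligomer is rendered one bead per residue
(chains stacked vertically, residues serpentine in-plane; designated
anchor residues can form the membrane-contacting face) and is rigid. Each
frame the protein is translated so its lowest bead sits exactly the
scheduled distance above the membrane's topmost lipid atom; because every
other membrane atom is lower and every other protein atom higher, the
scheduled value is realised *exactly* as the group minimum distance.
Before the planted binding time the schedule fluctuates uniformly in
[2.5, 5] nm — above the 2 nm contact threshold, so the detached phase
produces zero contacts and both detectors recover the planted time to one
frame spacing; after it, the schedule is the plateau (0.5 nm CG) plus
Gaussian noise truncated at ±2 sd (default sd 0.03 nm), keeping the bound
phase strictly below the 0.6 nm detection threshold. Chain tilts may be
resampled every frame from a given order target, so order-parameter
recovery averages over frames × molecules.

*Secondary structure.* Each residue-frame draws its category independently
from planted (beta, alpha, turn, random) fractions, then a concrete DSSP
letter within the category, making regrouped per-frame counts multinomial
around fractions × residues — the recovery tolerance is 3 standard errors
of that multinomial.

*Toy force field.* Martini-flavoured bead parameters (σ ≈ 0.47 nm,
ε ≈ 3–4.5 kJ/mol) with correct formal charges: PC/CHOL/water neutral, PS
and GM1 −1 on the head bead, protein beads carrying side-chain formal
charges (+1 Lys/Arg, −1 Asp/Glu). Both packaged monomers are net basic, so
Coulomb attraction to the anionic cluster dominates the protein–lipid
energy ranking, mirroring the anionic-lipid binding preference the
analyses are meant to resolve.

*What the fixtures do not emulate:* thermal disorder of headgroup
positions, lipid lateral diffusion and domain dynamics, protein
conformational change, solvent structure, or any force-balanced geometry.
Passing tests therefore certify the *analyses* (correct geometry,
bookkeeping and statistics against planted parameters and brute-force
oracles), not the emergent membrane biophysics of the original
simulations, whose headline numbers arise from microsecond MD and are not
reproducible at desk scale.

## Campaign orchestration

A campaign is oligomers × rafts × replicates; per-run seeds are derived
from a master seed by CRC-32 hashing of the stable run id (kept below
2³¹), so replicates are independent and the whole campaign reproduces
bit-for-bit. Per-run failures are caught, logged with a traceback and do
not stop the campaign. Outputs are plain TSV/JSON with a manifest.
Aggregation groups every tidy per-run table by its non-numeric key columns
and reports mean and across-replicate SEM per numeric column; conditions
with no completed run are flagged absent. Default problem sizes
(1/8-scale rafts, 30 frames per run) keep a full 12-run synthetic
campaign under a minute.

## Numerical notes and limitations

- Thresholded neighbour queries are inclusive (distance ≤ threshold);
  k-d-tree results at the exact boundary match the brute-force oracle to
  floating-point equality in the tests.
- Leaflet ties (reference z exactly at the midplane) resolve to the upper
  leaflet.
- SEM uses ddof = 1 across replicates; contact-map SD uses the population
  (ddof = 0) convention over frames.
- The spectrum/window question — stable-binding interval vs. fixed final
  window — is resolved by exposing the window as configuration, defaulting
  to the fixed tail (last 5 µs CG / 50 ns AA).
- Optional XTC/DCD ingestion goes through MDAnalysis behind the same
  trajectory contract; the text formats remain the reference path.
- No kinetic model fitting, no free energies (MM/PBSA is out of scope), no
  domain-size spatial statistics, no ANOVA — the pipeline reports
  mean ± SEM summaries only.
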