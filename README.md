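# oligoraft

Trajectory analysis of amyloid-oligomer binding to phase-separated raft
membranes.

Misfolded tau and amylin can cross-seed into hetero-oligomers whose first
encounter with the neuronal plasma membrane happens at functionalized lipid
nanodomains: liquid-ordered (Lo, saturated-PC + cholesterol-rich) patches
carrying anionic phosphatidylserine (PS) or ganglioside (GM1) clusters in a
single leaflet, surrounded by liquid-disordered (Ld, unsaturated-PC-rich)
membrane and a mixed Lo/Ld boundary (Lod). `oligoraft` implements, as a
tested and reusable pipeline, the analyses used to characterize such
protein–membrane encounters in coarse-grained and all-atom MD trajectories:

- **Phase-domain classification** — a PC lipid with any atom within 0.5 nm
  (minimum image, inclusive) of a PC of the other species is boundary
  (Lod); otherwise Lo (DPPC) or Ld (DLPC). Cholesterol inherits the label
  of the phase(s) it touches. Compositions are reported as percentages with
  SEM over replicates.
- **Binding kinetics** — group minimum distance (*mindist*) and atom-contact
  counts (threshold 2 nm) vs. time; the lipid-binding time is the onset of
  the persistent low-mindist plateau.
- **Mindist spectra** — per-residue, time-, chain- and replicate-averaged
  minimum distances, with optional 5-point moving-average smoothing.
- **Annular lipids** — the AL shell is every lipid with an atom within
  0.5 nm of the protein; per-type AL percentages.
- **Chain order profiles** — S(n) = ⟨P₂(cos θₙ)⟩ of the local chain axis
  C(n−1)→C(n+1) against the bilayer normal, per lipid type, chain
  (sn-1/sn-2) and shell (AL/nAL).
- **Nonbonded energetics** — 12-6 Lennard-Jones plus vacuum Coulomb summed
  over cross-group pairs within a plain 1.2 nm cutoff (Lorentz–Berthelot
  combining), resolved interchain and per lipid type.
- **Protein structure** — Kyte–Doolittle hydropathy profiles, DSSP-code
  regrouping (beta ← {E,B}, alpha ← {H,G,I}, turn ← {T}, random ← {S,C}),
  and residue–residue contact maps with time-mean and SD.
- **Synthetic generator** — phase-separated asymmetric raft fixtures,
  binding trajectories and secondary-structure streams with planted ground
  truth, standing in for MD output so that every analysis can be closed
  against known parameters.

## Worked example

```python
from oligoraft import synthetic as syn, binding, domains, energetics as en

spec = syn.RaftSpec.from_raft_type("PS", scale=8, seed=0)   # reduced PS-raft
system = syn.assemble_complex(syn.build_raft(spec), "1tam") # tau–amylin dimer
traj = syn.generate_binding_trajectory(
    system, syn.TrajectorySpec(n_frames=30, frame_spacing=0.5, t_bind=3.0, seed=0))

ms = binding.mindist_series(traj, "protein", "POPS")
print("binding time:", binding.detect_binding_time(ms, d_bind=0.6), "us")
print("plateau mindist:", round(float(ms.values[-5:].mean()), 3), "nm")

comp = domains.domain_composition([traj], window=5.0)
print(comp.table)

df = en.protein_lipidtype_energy([traj], syn.emit_forcefield_table(), window=5.0)
print(df[["lipid_type", "e_lj", "e_coulomb", "e_total"]].round(1))
```

prints

```
binding time: 3.0 us
plateau mindist: 0.489 nm
species  domain   percent
   CHOL      Lo 58.333333
   CHOL      Ld 13.888889
   CHOL     Lod 27.777778
     PC Lo-DPPC 39.072848
     PC Ld-DLPC 27.814570
     PC  Lod-PC 33.112583
lipid_type   e_lj  e_coulomb  e_total
      DPPC  -50.9        0.0    -50.9
      DLPC  -35.1        0.0    -35.1
      CHOL  -31.0        0.0    -31.0
      POPS -149.6    -1025.8  -1175.3
```

The detector recovers the planted 3 µs binding time exactly; the bound
plateau sits at the planted ~0.5 nm; the domain triples each sum to 100%;
and the protein–POPS interaction dominates (the oligomer binds over the
anionic cluster, and Coulomb attraction to the −1 PS headgroups adds to the
contact Lennard-Jones term), mirroring the anionic-lipid preference the
pipeline is designed to resolve.

A CLI wraps the same stages: `oligoraft generate` (synthetic fixture sets),
`oligoraft analyze` (one structure + trajectory), `oligoraft campaign`
(the full oligomer × raft × replicate table) and `oligoraft aggregate`
(replicate means ± SEM).

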