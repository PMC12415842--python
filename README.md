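# condensekit

Trajectory-analysis toolkit for biomolecular condensates and multidomain
disordered proteins. It implements, as reusable tested code:

- **Summed heavy-atom contacts** — residue-pair contact counts (number of
  heavy-atom pairs within 4.5 Å, strict `<`, same-chain pairs within a
  five-residue proximity window excluded), ensemble maps with
  intra-/inter-molecular channels, 1-D position profiles, domain-block
  aggregation, residue-type contact-ratio tables (210 unordered type-pair
  bins) and per-type normalized contacts, and dilute-vs-dense contact
  correlations.
- **sp²-plane stacking statistics** — the angle–distance pair correlation
  g(r, θ) between Phe phenyl-ring and Arg guanidinium plane normals
  (0.6 Å × 2.5° bins), corrected by the exact per-bin integral of the
  r² sin θ volume element; Zn–S distance and Zn–S–Cβ angle reports.
- **Chain-dimension metrics** — mass-weighted Rg, Cα end-to-end distance,
  FFT autocorrelation with Sokal-windowed integrated autocorrelation time
  and an equilibration suggestion, a convex-hull hydrodynamic radius
  (hydration-shell + Perrin shape correction), Kabsch RMSD (proper
  rotations only) and iteratively superposed RMSF.
- **Slab profiles** — per-component mass-density (mg/mL) and molar (mM)
  profiles along z with protein-COM recentering, dense/dilute phase
  assignment, and an electroneutrality-based prediction of Na⁺/Cl⁻
  partitioning from local charged-residue concentrations.
- **Flat-bottom restraints** — the C¹-continuous flat-bottom pair potential
  (harmonic outside [r0, r1], linear beyond r2), analytic forces,
  geometric hydrogen-bond pair derivation from (multi-model) structures,
  and deterministic TSV export/import.
- **Synthetic data** — seed-reproducible generators for single chains
  (freely-jointed Cα backbone, rigid folded-domain templates, planted
  residue contacts realized as exact-bond-length bridges, planted
  phenyl/guanidinium stacks) and multi-chain slabs with pseudo-water and
  ions carrying plantable dense-phase excesses. Everything the test-suite
  consumes is generated programmatically.

Internal units: Å, amu, ps; restraint parameters are in nm (their
conventional unit) at the restraint-module boundary.

## CLI

```bash
# generate a synthetic system from a YAML spec
condensekit synth spec.yaml --out chain.pdb            # or --kind slab

# analyses (all read multi-model PDB)
condensekit contacts chain.pdb --out out/contacts --cutoff 4.5 --exclusion 4
condensekit stacking slab.pdb --out out/g.tsv --rmax 12 --rbin 0.6 --abin 2.5
condensekit dimensions chain.pdb --out out/dim.tsv
condensekit slab slab.pdb --out out/profile.tsv --bin 2.5 --bulk-salt-mm 150
condensekit restraints native.pdb --out out/restraints.tsv --cutoff 3.5

# full report bundles (TSV + JSON + deterministic manifest)
condensekit report chain1.pdb chain2.pdb --out-dir out/single \
    --domain-map domains.tsv --folded RRM,ZnF
condensekit report slab.pdb --out-dir out/slab --kind slab
```

A domain map is a 3-column TSV (`name<TAB>first<TAB>last`, 1-based,
inclusive). Synthetic specs are YAML/JSON mirroring
`condensekit.synthetic.SyntheticSpec`.

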