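# hybridem

Hybrid structural-model assembly for multi-domain complexes whose
structure is only partly covered by any single experiment — the
motivating system is bacterial multi-subunit RNA polymerase, where
*lineage-specific inserts* (sequence segments present in some bacterial
lineages and absent in others, spliced between universally shared
regions of the large subunits) are missing from the best crystallographic
template and must be assembled in from fragment structures, predicted
models and cryo-EM density.

The package implements that workflow as a tested, reusable pipeline:

1. **Homology scaffold** — copy template backbone onto the target
   numbering from a pairwise alignment, leaving target-specific inserts
   as gaps and omitting template-specific inserts (closed by short built
   loops with Cα spacing held in the 2.9–4.1 Å band).
2. **Fragment splicing** — rigid superposition of a fragment structure's
   shared anchor domain onto the scaffold (least-squares Kabsch solution,
   reflections rejected), then atom-exact replacement of the anchor +
   insert region.
3. **Toy-scale single-particle reconstruction** — reference projections
   on a quasi-uniform sphere grid, exhaustive normalized
   cross-correlation projection matching (ZYZ Euler convention,
   R = R_z(φ)·R_y(θ)·R_z(ψ)), ramp-weighted back-projection, iterative
   refinement with half-set Fourier shell correlation (FSC) diagnostics,
   and the hyperbolic-tangent low-pass filter
   H(f) ∝ ½[tanh(π(f+f_s)/(2·w·f_s)) − tanh(π(f−f_s)/(2·w·f_s))].
4. **Rigid density fitting** — exhaustive rotation grid + FFT translation
   scan, local refinement on the model–map cross-correlation, and
   *linker feasibility* screening: a placement can only bridge to its
   sequence anchors if every anchor span ≤ 3.8 Å × (missing residues + 1).
   This disambiguates pseudo-symmetric inserts that fit their density
   equally well in two orientations.
5. **Flexible fitting** — Cα elastic-network model (uniform springs
   within 12 Å) ascending the density gradient under an annealed weight
   schedule, with frozen selections and a best-correlation snapshot so
   the final model–map CC never drops below the start.
6. **Conservation analysis** — MSF/FASTA alignments, residue-number →
   column mapping through a reference row, residue-class fractions
   (gap rows count in the denominator), a rescaled mean-pairwise
   BLOSUM62 information score, and insertion-location profiles.

A seeded synthetic generator (`hybridem.synthetic`) produces a
"mini-polymerase" with complete ground truth — template, target with
inserts, displaced fragments, density maps, particle stacks, and
alignments with prescribed conservation — so every stage is tested as a
parameter-recovery problem.

## Worked example

Assemble the synthetic system end to end — scaffold from the template,
close the template-insert gap, splice the fragment, flexible-fit into
the simulated map — and compare with ground truth:

```bash
$ hybridem assemble --seed 3 --out assembled.pdb
cc scaffold 0.9986829389549212 → final 0.9991689858875368
Cα RMSD to ground truth: 0.45 Å (report e01d992d4715302f)
```

The scaffold already fits the density well (CC 0.9987, since the
template core diverges from the target by only ~0.25 Å per coordinate);
flexible fitting nudges it to CC 0.9992, and the final model is 0.45 Å
(Cα) from the generator's ground truth. The report hash is
deterministic for a given seed.

Library use mirrors the CLI:

```python
from hybridem import synthetic, pipeline

manifest = synthetic.make_toy_system(synthetic.ToySystemSpec(seed=3))
density = synthetic.make_map(manifest)
config = pipeline.config_from_manifest(manifest, density=density, seed=3)
model, report = pipeline.run_assembly(config)
```

Other subcommands: `hybridem synth` (write the synthetic system to
disk), `measure` (domain extents, reach, interval lengths), `conserve`
(per-position class fractions of an alignment), `reconstruct`
(projection-matching refinement of a particle stack), `fit-rigid` and
`fit-flex`.

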