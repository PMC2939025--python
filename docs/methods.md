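# Methods

This note records the models, conventions and numerical choices behind
`hybridem`, in the spirit of a software methods section: what each stage
assumes, which knobs matter, and what the synthetic benchmarks do and do
not demonstrate.

## Coordinate and orientation conventions

Coordinates are Å in a right-handed frame. Author residue numbering is
preserved verbatim through every operation, because domain and insert
boundaries are always communicated as author-numbered intervals
(inclusive; length = last − first + 1). Density maps are stored with
X/Y/Z axis order, an isotropic voxel size and an origin in Å;
MRC/CCP4 files with a different column/row/section order are permuted on
read, and non-isotropic cells are rejected rather than silently
resampled.

Projection orientations use intrinsic ZYZ Euler angles
(R = R_z(φ)·R_y(θ)·R_z(ψ), degrees, θ ∈ [0°, 180°]), the convention of
classic single-particle packages. A particle image is the line integral
of the volume along R·ẑ after sampling the volume at R·o for image
points o; ψ is in-plane rotation, and (x, y) shifts in voxels apply to
the projected image. Under this definition
(φ, θ, ψ) → (φ+180°, 180°−θ, −ψ) gives the mirror of the same view,
which the test suite checks numerically.

## Homology scaffold and splicing

The scaffold copies backbone atoms (N, CA, C, O, CB where present) for
every aligned template↔target residue pair and renumbers them to the
target. Target-side insert gaps are returned for downstream splicing or
placement; template-side inserts are omitted. Side-chain building is
deliberately out of scope: splicing, grafting and fitting operate on
backbone/Cα geometry, and full-atom fragments pass through untouched.

Gap closure builds bridge loops as Cα-only traces: even interpolation
between the flanking anchor Cα atoms, followed by a short deterministic
relaxation that pushes consecutive spacing into the 2.9–4.1 Å band
(bowing the trace perpendicular to the chord when the anchors are too
close). 4.1 Å is a generous trans-peptide Cα–Cα spacing; a closure is
declared infeasible when the anchor span exceeds 4.1 Å × (bridge
length + 1). Built residues carry occupancy 0.0 so measurements can
exclude them.

Splicing superposes the fragment's shared anchor domain onto the
scaffold using Cα atoms only (robust to side-chain differences between
crystal forms) via the least-squares Kabsch solution with reflection
correction (`scipy.spatial.transform.Rotation.align_vectors`). A
shared-region RMSD above 5 Å aborts the splice — that guard exists to
catch wrong-domain correspondence lists, and the unit tests trigger it
with a scrambled correspondence. Atom bookkeeping is exact:
|result| = |scaffold| − removed + inserted.

## Density simulation, filtering and FSC

Simulated density places one unit-weight isotropic Gaussian per
non-hydrogen atom with FWHM equal to the nominal resolution
(σ = FWHM/2.355), implemented as a trilinear splat followed by a
Gaussian convolution, so the grid integral is proportional to the atom
count. The Nyquist guard requires resolution ≥ 2 × voxel size.

The hyperbolic-tangent low-pass filter uses the radial transfer function

    H(f) ∝ ½ [tanh(π(f+f_s)/(2·w·f_s)) − tanh(π(f−f_s)/(2·w·f_s))],

with the stop band f_s in cycles/voxel and dimensionless fall-off w, the
form popularized by the SPARX package — quoted parameter pairs such as
(0.28, 0.45) plug in directly. H is normalized by its value at f = 0 so
the DC term passes exactly; without that normalization H(0) for
(0.28, 0.45) is 0.9981, and a "constant map in, constant map out"
contract would silently fail.

FSC uses shells one Fourier voxel wide; the resolution at a threshold is
the linearly interpolated first downward crossing, reported as
voxel_size / f_cross in Å, with the Nyquist wavelength (2 × voxel)
returned when the curve never crosses. σ-contour levels are computed
over the whole unmasked grid (mean + n·sd), matching how map viewers
report them.

## Projection matching and reconstruction

Reference projections sample a quasi-uniform sphere grid: θ at the
angular step, φ at step/sin θ per θ-row, poles once. Matching is
exhaustive normalized cross-correlation over the reference grid × an
in-plane ψ grid × integer shifts within a radius (default ±1 voxel),
with ties broken to the lowest library index. Both references and
images can be band-limited before matching (tanh stop band, default
0.3 cycles/pixel in the refinement loop): with additive white noise,
frequencies beyond the signal's resolution contribute only noise to the
correlation, and removing them raises the fraction of correct
assignments materially at SNR 1.

Back-projection is real-space with a per-image 2-D ramp (|f|) filter —
the standard density compensation for uniformly distributed views — and
is normalized as the mean over images, so duplicating the image set is a
no-op. Iterative refinement rebuilds references from the current volume
each iteration, reassigns every image, back-projects, and records the
mean match score, the half-set FSC-0.5 resolution (even/odd image
split), and the median viewing-direction error when ground truth is
attached. A divergence guard stops after two consecutive drops of the
mean score larger than 10⁻³ (smaller fluctuations are plateau jitter,
not divergence). The half-set FSC resolution itself has a granularity of
about one Fourier shell at the crossing frequency; monotonicity checks
in the tests allow exactly that much slack.

CTF effects are omitted entirely: synthetic images are CTF-free with
additive Gaussian noise, and SNR is defined as signal variance / noise
variance per image over all pixels.

## Rigid fitting and linker feasibility

The coarse search enumerates an SO(3) grid (sphere directions × in-plane
angles at the same step) and, for each rotation, finds the best
translation by FFT cross-correlation between the target map and a map
simulated from the rotated fragment. The top candidates are refined
locally (Nelder–Mead on six rigid parameters) against the normalized
model–map cross-correlation, computed over voxels where the simulated
fragment density exceeds 10 % of its maximum — masking keeps empty
regions from diluting the score, and the Pearson form makes it invariant
to affine rescaling of either map. Refined placements within 5° and one
voxel of an already-kept placement are treated as duplicates.

Each placement is screened for linker feasibility: span between the
scaffold anchor Cα and the placed fragment's terminal Cα must not exceed
3.8 Å (the Cα virtual-bond length) per missing residue plus one, for
every linker. Feasible placements are ranked by CC; infeasible ones are
returned in a separate ranked list so a failed search is never silent.
The two-lobe benchmark builds a near-C2-symmetric two-helix fragment
whose density is fit equally well (CC > 0.95) by two orientations 180°
apart; only one can bridge its sequence anchors, reproducing the
orientation-disambiguation logic used for pseudo-symmetric inserts
interrupting the trigger loop.

## Flexible fitting

Cα nodes form an elastic network with uniform unit springs inside a
12 Å cutoff; rest lengths come from the input model, and the network
must be a single connected component. Nodes ascend the gradient of the
σ-normalized map (trilinear interpolation of a central-difference
gradient) against the spring forces, with an annealed density-weight
schedule (0.5, 1.0, 1.5; one phase each, 300 steps total). The
σ-normalization puts density forces on the same scale as unit springs,
which is what makes the weight schedule meaningful. Steps use a soft
per-node normalization — displacement = cap · f/(|f| + median |f|), cap
0.3 Å — so strong-force nodes move near the cap and weak-force nodes
proportionally less, without a global scale choice. Frozen residues are
pinned exactly; non-Cα atoms ride with their residue's Cα displacement.

Every 10 steps the model–map CC is evaluated and the best snapshot kept;
the returned model is that snapshot, which guarantees the final CC is
never below the initial one even if a late annealing phase overshoots.
Strain energies (½·k·Σ(d−d₀)²) of the start and the returned model are
reported; because rest lengths are taken from the input, the start
strain is zero and the guard against map-tearing is the absolute final
strain per spring rather than a ratio. The 12 Å cutoff matters: with a
10 Å network the insert in the hinge benchmark is too loosely coupled to
the (well-placed) core and recovery stalls near 50 %; at 12 Å the
benchmark recovers ~80 % of the bent-model RMSD.

## Conservation scoring

"% of sequences" counts gap rows in the denominator — a sequence that
lacks the position does not conserve it — with the gap-excluded variant
reported alongside, since either convention appears in the literature.
The BLOSUM62 information score is a stand-in for the viewer-style score
whose exact formula is not published: mean pairwise BLOSUM62 similarity
over non-gap pairs, each pair affinely rescaled between the matrix
minimum (→ 0) and the smaller of the two self-similarities (→ 1),
multiplied by column coverage. Exactness is claimed only at the
endpoints: an identical gap-free column of any residue scores 1, and a
column pairing the most dissimilar residues scores 0. Insertion
profiles report, for each maximal run of reference-row gap columns, the
author-numbered reference position preceding the run and the longest
insertion any single row places in it.

## The synthetic mini-polymerase

The generator is a pure function of spec + seed. The core is a bundle
of ideal α-helices (rise 1.5 Å, 100° twist, 2.3 Å Cα radius) with
tapered lengths (24, 18, 14, 10 residues), 10 Å row spacing, and a 6 Å
z-staircase plus 3 Å x-skew between successive domains; 3-residue
relaxed loops connect them. The taper and staircase are deliberate:
orientation assignment is only a well-posed benchmark for a particle
with no approximate mirror symmetry, and the skew keeps connector spans
near 12 Å so 3-residue loops bridge them at plausible spacing. Inserts
are out-and-back hairpin traces attached in the connector loops (as
lineage-specific inserts sit between shared regions), tilted away from
the helix rows so their legs clear neighbouring domains; a guard rejects
any spec whose insert/bridge atoms come within 2.5 Å of the rest of the
chain. The ground-truth geometry is seed-independent; the seed drives
residue identities, the template's 0.25 Å core divergence, fragment
perturbation (0.3 Å) and displacement, particle orientations and noise,
and alignment sampling.

Default imaging conditions: 32³ volumes at 2.0 Å voxels (the ~40 Å
particle fills about 60 % of the box, similar to typical windowing
practice), maps simulated at 10 Å (15 Å for the flexible-fitting
benchmark), stacks of 400–500 particles at SNR 1.0. Everything runs in
seconds to a couple of minutes on one CPU; these sizes were chosen as
the smallest at which the estimators behave stably, and all tolerances
were fixed alongside them.

What the synthetic benchmarks show: that each stage recovers known
ground truth under its stated noise model, and that the stages compose.
What they do not show: behaviour on real micrographs (no CTF, no ice or
background gradients, no picking errors), real homology divergence
(template/target differ by noise, not by conformational change or
side-chain packing), or real sequence evolution (alignment columns are
i.i.d. draws around a consensus, with no phylogenetic correlation).

## Published-data checks

Measurements that require the deposited coordinate sets and
supplementary alignments (superposition RMSD of the shared β2 domain,
buried interface area, closest-approach distances in the elongation
complex, insert extents, alignment row counts and basic-residue
fractions) are implemented and run against files the user places under
`data/paper/`; the exact residue subset behind the "~100 residues,
loops excluded" superposition is supplied as a fixture file rather than
hard-coded, since it is not enumerated anywhere. Buried area is
reported both as SASA(A)+SASA(B)−SASA(A∪B) and as half that value, and
the deposited-data check accepts whichever convention matches, because
the printed number's convention is unstated.

## Known limitations

- Loops are Cα traces with plausible spacing, not stereochemically
  refined backbones.
- The ENM flexible fit has no secondary-structure restraints; very
  large motions can shear the network (the best-CC snapshot bounds the
  damage but does not prevent it).
- The rigid-fit translation scan is voxel-quantized before local
  refinement; fragments smaller than a few voxels may alias.
- SASA uses a fixed element→radius table; exotic elements must be added
  to `SasaParams.radii` explicitly.
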