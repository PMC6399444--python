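# Methods

`sercatools` implements the trajectory-analysis battery used to compare a
lipid-bound and a lipid-free simulation of a P-type calcium pump (SERCA):
contact and hydrogen-bond occupancies, distance probability distributions
against crystal-structure references, per-helix RMSD profiles,
conformational clustering of a mobile lipid headgroup, Cartesian principal
component analysis (cPCA) with an r²-based essential-space classifier and
inner-product collinearity, and hydrogen-bonded water-wire detection.
This note records the models, the conventions behind every tunable
parameter, what the synthetic generators do and do not emulate, and the
numerical choices.

## Units and data model

Internal units are nanometres and nanoseconds throughout; frame intervals
and wire lifetimes are quoted in picoseconds, matching how such quantities
are conventionally reported. PDB ångströms are converted at the I/O
boundary. Residue numbering is 1-based and follows the source structure's
numbering, so SERCA1a labels (Gln56, Asn101, Gln108, Glu109, Lys246,
Glu309, Thr316, Asp800, Glu908, Val223, Lys515, Asp351) work verbatim in
selections. Atoms carry one of four categories (protein / lipid / water /
ion) assigned from residue names; unrecognized residue names fall into the
lipid bucket, which doubles as the generic organic-molecule category.

Trajectory frame intervals are metadata only. The saving interval of a
source simulation cannot be inferred from coordinates, so it is declared
by the caller and never guessed; when declared, frame times must be
uniform to 1e-9 relative tolerance.

Helix and domain definitions (M1–M10, N/P/A domains, the TM composite and
the cytosolic headpiece) come from a YAML segment map, not code. The
shipped default uses literature-conventional SERCA1a boundaries; any
analysis that cares about exact boundaries should supply its own map.

## Distances, occupancies, hydrogen bonds

Distance observables come in three modes: minimum over heavy-atom pairs,
named-atom (both selections singletons), and centre-of-geometry. The
orthorhombic minimum-image convention applies whenever a frame declares a
box. Occupancy intervals are closed on both ends, so the customary
"R ≤ 0.5 nm" criterion is expressed as [0, 0.5] with the boundary
included.

The named-atom conventions shipped for headgroup pairs are: choline ≡ the
lipid nitrogen, phosphate ≡ the lipid phosphorus, Gln/Asn ≡ side-chain
amide N/O, Thr ≡ hydroxyl oxygen, Glu ≡ carboxyl oxygens, Lys ≡ NZ, and
Cα for interdomain distances. These are field conventions, configurable
per analysis; crystal-reference distances computed under them inherit an
atom-convention uncertainty of roughly ±0.1 nm.

Hydrogen bonds default to donor–acceptor heavy-atom distance ≤ 0.35 nm
and donor–H–acceptor angle ≥ 150°, the values most MD analysis tools use.
Hydrogens are optional in topologies: when absent, the criterion degrades
to distance-only and the result's criterion string records the fallback
explicitly. Covalent donor hydrogens are identified by a 0.125 nm
distance cutoff.

Histograms are density-normalized (∫ = 1) with edges snapped to multiples
of the bin width; the default width of 0.025 nm resolves peak separations
of ~0.3 nm, the scale at which bimodal contact distributions in this
system differ.

## Superposition, RMSD, clustering

Superposition uses the closed-form least-squares optimal rotation (the
Kabsch/quaternion family, via `scipy.spatial.transform.Rotation.
align_vectors`), which is deterministic and exact to floating point. Fits
require ≥ 3 non-collinear atoms. Per-helix RMSD profiles fit each frame on
the all-TM backbone and measure each helix over its backbone atoms without
refitting; headpiece RMSD time series fit and measure on the headpiece
backbone. Whether per-helix profiles should use backbone or all heavy
atoms is genuinely open; backbone is the shipped default and both are
configurable.

Conformational clustering is leader clustering on pairwise RMSD (frames
scanned in order, assigned to the first cluster whose founding frame is
within the cutoff) followed by medoid re-assignment of representatives.
Leader clustering was chosen because it is deterministic given frame
order, which testing requires; the default cutoff is 0.1 nm over the
headgroup heavy atoms. Frames are assumed pre-aligned on a fit selection
of the caller's choosing, so cluster distances are plain RMSD without
refit.

## Cartesian PCA and the essential-space classifier

After optional per-frame superposition on a reference (conventionally the
ten-helix TM domain), the 3N-dimensional covariance of the selected
atoms' coordinates is eigendecomposed. Components are ordered by
descending eigenvalue; each eigenvector's sign is fixed by making its
largest-magnitude entry positive so that results are reproducible (inner
products use absolute values and are sign-independent anyway).
Eigenvalues with relative gaps < 1e-6 are flagged degenerate; under
degeneracy individual-vector collinearity is ill-defined and subspace
comparisons (row norms of the inner-product matrix) should be used
instead.

The default atom set for PCA is Cα of the analyzed selection — the
standard essential-dynamics choice, which keeps covariance sizes
desk-scale; backbone and heavy-atom sets are configuration options since
the underlying convention cannot be adjudicated from published figures.

Each component's projection histogram (50 bins over mean ± 4 sd; bin
count chosen so the classifier's sampling behaviour is stable at the
sample sizes used in the tests) is least-squares fitted with one Gaussian
(amplitude, µ, σ) and r² = 1 − SS_res/SS_tot computed over bin densities.
Classification bands: r² < 0.9 essential (markedly non-Gaussian
collective motion), 0.9 ≤ r² < 0.98 partial (retains significant
non-Gaussian features), r² ≥ 0.98 non-essential (Gaussian fluctuation).
A non-convergent fit withholds classification and reports diagnostics
rather than guessing.

## Water wires

A water wire is any configuration of hydrogen-bonded waters connecting a
source site (e.g. the carboxyl oxygens of a buried protonated glutamate)
to a sink site (e.g. a carboxamide group at the cytosolic mouth of the
pore) or to bulk solvent past a z-boundary plane. The per-frame call is
binary — wire or no wire — irrespective of how many hydrogen-bonded
configurations exist or which waters participate. Detection is BFS over
the H-bond graph with deterministic (ascending atom index) ordering;
only path existence matters. A direct source–sink hydrogen bond counts
as a zero-water connection. Defaults: at most 4 bridging waters (observed
wires in this system have 3; the bound is configurable headroom), and a
candidate-water pre-filter keeping waters within a 0.8 nm-radius cylinder
around the source→sink axis, standing in for a narrow interhelical
pathway that has no crisp geometric definition. The N-terminal
(Glu309→Asn101) and C-terminal (Glu309→Asp800/Glu908) pathways are two
configurations of the same machinery, not separate code.

Maximal runs of wire frames form events; runs separated by at most
`gap_merge_frames` wire-less frames are merged (default 0: an event is an
uninterrupted run — the merge parameter exists because event segmentation
has no canonical rule). Lifetimes are inclusive frame counts × frame
interval, in ps.

## Synthetic generators

Every generator is a pure function of its spec (same seed → bit-identical
output) and returns planted ground truth alongside the fixture, so tests
recover parameters rather than re-deriving them.

* **Distance process** — hidden-state Markov chain with Gaussian emission
  per state. With probability `transition_rate` the chain resamples its
  state from the stationary weights (else it stays), making the
  stationary law exactly the declared weights for any number of states.
  The default rate of 0.5 models frames saved at intervals comparable to
  the contact correlation time, so successive frames are nearly
  independent and occupancy estimates carry close to binomial error.
* **Planted-covariance trajectories** — frames are mean + Σₖ aₖ(t)·vₖ
  with a random orthonormal basis; Gaussian amplitudes with variance =
  eigenvalue, except components flagged non-Gaussian, which draw from
  equal-weight wells at ±3σ_well with offset² + σ_well² = eigenvalue
  (total planted variance preserved; the ±3σ two-well shape reliably
  defeats a one-Gaussian fit, r² < 0.9).
* **Wire schedules** — during on-windows, three (configurable) chain
  waters sit on the source→sink axis at 0.28 nm O–O spacing, safely
  inside the 0.35 nm cutoff; off-window they are parked mutually > 0.6 nm
  apart and > 0.6 nm from the sites. Decoy bulk waters never come within
  H-bond range of anything. Ground truth is unambiguous by construction.
* **State-hopping trajectories** — frames hop i.i.d. between k rigidly
  displaced copies of one structure (inter-state RMSD ≥ the declared
  separation), emulating the discrete orientations of a mobile headgroup,
  including a < 8% minority state.
* **Paired demo systems** — one topology combining a planted contact
  probe, a wire subsystem, a planted-covariance block and a state-hopping
  block, generated as a "bound"/"free" pair with different planted
  parameters, written as PDB + XYZ text with a JSON ground-truth
  manifest.

What the generators deliberately do **not** emulate: force-field
energetics, solvent structure, autocorrelated conformational kinetics
beyond the two-state switching, anisotropic or correlated noise, and
crystallographic artefacts. Passing tests therefore demonstrate that the
analysis machinery measures what it claims on data whose statistical
structure is known — not that any scientific conclusion about real
trajectories is reproduced. Headline numbers from microsecond simulations
(event counts such as 6 vs 8, occupancies of 71%/89%/~6%) depend on
undeposited data and are out of reach by construction; the tests verify
the machinery, at desk scale (typically 2,000–20,000 frames, seconds to
a minute per check).

Fixture PDB coordinates are quantized to the format's printed precision
(0.001 Å) at generation time, so structure round trips are exact rather
than carrying the format's ~5e-5 nm rounding error.

## Degenerate inputs and error behaviour

Empty selections, empty series, zero-variance correlations, < 3-atom or
collinear superposition fits, < 2-frame PCA, out-of-range components and
malformed files all raise typed errors naming the offending input (file
errors name the line, trajectory shape errors the frame index). The
pipeline validates every selection against the topology before any
computation and aborts with the stage name on failure.

## Known limitations

* The H-bond angle term needs hydrogens; heavy-atom-only topologies get
  the distance-only fallback (recorded, but weaker).
* Minimum-image support is orthorhombic only; no general triclinic cells
  and no trajectory unwrapping.
* Leader clustering depends on frame order by design; only on
  well-separated state structures is the partition order-invariant.
* The crystal worked value (Gln108–Thr316 ≈ 0.65 nm) requires a local
  copy of the public 2agv coordinates at `data/2agv.pdb`; the repository
  does not bundle them, so that one check reports only when the file is
  supplied.
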