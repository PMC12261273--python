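# Methods

This note documents the models and procedures implemented in `aptadyn`,
their assumptions and tunable parameters, the design choices made where the
design was genuinely open, and what the synthetic test systems do and do
not demonstrate about real aptamer trajectories.

## Secondary-structure scoring

A *given* pseudoknot-free fold is decomposed into its loops: adjacent base
pairs contribute Watson–Crick stack increments, unpaired regions contribute
hairpin/bulge/internal-loop penalties indexed by loop size, multiloops
contribute `a + b·branches + c·unpaired` (defaults 4.6 / 0.4 / 0.1
kcal/mol), and each exterior-facing helix end closed by an A·T pair pays a
terminal correction. The bundled table is a unified DNA nearest-neighbor
set (ΔG°37 with ΔH/ΔS for the ten unique stacks, referenced to 1 M Na⁺);
temperatures other than 310.15 K rescale stacks through ΔH − TΔS and
loops proportionally to T (loops are treated as purely entropic), and a
monovalent-salt correction of 0.368·ln[Na⁺] cal mol⁻¹ K⁻¹ is applied per
stack. Stack motifs are canonicalized by the top-strand dinucleotide
(`min(step, revcomp(step))`), which removes any dependence on which strand
a step is read from. Loop sizes between table entries are interpolated
linearly in ln(size) and extrapolated beyond the table with the
Jacobson–Stockmayer form ΔG(n) = ΔG(n_max) + 2.44·RT·ln(n/n_max).

Deliberate simplifications: single-bulge steps score only the bulge
penalty (no through-stack bonus); noncanonical pairs are accepted but
contribute no stack energy (they matter for MD contact analysis, not for
NN scoring); minimum-free-energy *prediction* is out of scope — candidate
folds come from external servers and the package's job is consistent
relative ranking, not reproducing any particular server's absolute ΔG.

## Superposition and mobility

All fits are Kabsch least-squares superpositions via SVD, with the proper
rotation enforced by the determinant correction; the residual RMSD is
computed from the transformed coordinates rather than the singular-value
identity, which loses about eight digits to cancellation near a perfect
fit. Segment RMSD profiles fit *on the segment* (segment-local
superposition), so an internally rigid motif shows a flat profile even
when it hinges or tumbles relative to the rest of the molecule — this is
what makes "the core keeps its internal conformation while the terminus
rearranges" an observable statement.

Per-residue RMSF is the per-atom root-mean-square fluctuation about the
time-averaged structure, averaged within the residue. Because a single
global fit lets an atom-rich floppy terminus drag the superposition and
inflate the apparent mobility of the rigid core, RMSF for truncation
evidence is computed after aligning on a rigid core chosen by an
alignment-free *distance-fluctuation* score: for each residue, the median
over partners of the standard deviation of the C1′–C1′ distance. Residues
embedded in a rigid body relative to most of the molecule score low; the
measure cannot be fooled by the superposition itself. The lowest-scoring
half of the residues (minimum three) forms the fit core.

## Contact annotation

Hydrogen bonds are detected between name-tabulated base-edge donors and
acceptors of residue pairs at least 2 apart in sequence. With explicit
hydrogens the criterion is donor–acceptor distance ≤ 3.5 Å and D–H···A
angle ≥ 135°; for heavy-atom-only inputs (including all bundled fixtures)
it is distance-only ≤ 3.4 Å. A residue pair is reported as a *canonical*
base pair when every bond of the complementary Watson–Crick pattern (three
for G·C, two for A·T) is simultaneously satisfied; abundance is the exact
percentage of frames in which that joint event holds. Stacking requires
ring-centroid distance ≤ 4.5 Å, interplanar angle ≤ 30° (plane normals
from an SVD plane fit of the ring atoms) and lateral centroid offset
≤ 2.5 Å. Records below 5 % abundance are omitted by default; every cutoff
is a parameter of `ContactParams`. The reported 2.8–3.0 Å mean distances
of persistent pairs are outcomes of the geometry, not the detection
cutoff.

## Clustering

Frames are compared by mask RMSD with per-pair optimal superposition (no
shared pre-alignment), merged by average linkage, and the hierarchy is cut
where the smallest inter-cluster average distance exceeds ε. Average
linkage is monotone, so cutting the scipy dendrogram at ε is exactly the
ε-stopping merge loop; the test suite verifies this equivalence against a
naive merge implementation exhaustively on small inputs. Clusters are
renumbered by descending population with ties resolved toward the cluster
containing the lowest frame index; a cluster's representative minimizes
the mean RMSD to its other members (ties to the lowest index). The
(cluster count, population entropy) pair serves as the flexibility
indicator: a rigid molecule collapses to one cluster (entropy 0), a floppy
one fragments. Pairwise distance matrices are O(n²); a stride parameter
keeps desk-scale inputs in the low thousands of frames.

## Boosted-sampling reweighting

With a non-negative boost ΔV added to the potential, the canonical PMF
over binned collective variables is recovered per bin j by the cumulant
expansion F(j) = −kT[ln p*(j) + β⟨ΔV⟩ⱼ + β²σ²ⱼ/2] + C (second order by
default, first order available as a diagnostic; k_B = 0.0019872041
kcal mol⁻¹ K⁻¹). The second-order form is exact when ΔV is Gaussian
within a bin — the working regime of Gaussian-accelerated sampling, and
the regime the boost-statistics skewness diagnostic is meant to confirm.
Bins with fewer than `min_samples` frames (default 10; default 50 bins
per axis, at most two axes) are masked rather than extrapolated, and the
minimum over unmasked bins is shifted to zero. A consequence worth noting:
free-energy *differences* between well-sampled bins are invariant under
duplicating the data, but the zero point can move if extra sparse bins
cross the masking threshold. Collective variables are supplied by the
caller; the module does not choose them.

## End-point energetics (MM-GB/SA)

Single-trajectory, solute-only scoring: Coulomb (332.0637 kcal Å mol⁻¹
e⁻²) and Lennard-Jones 12-6 terms over nonbonded pairs with 1-2/1-3
exclusions and AMBER-style 1-4 scaling (elec 1/1.2, vdW 1/2, both
configurable), no cutoff by default at desk scale; an OBC-type
generalized-Born polar term; and a nonpolar term γ·SASA + b (Shrake–Rupley
quadrature, 960 sphere points ≈ 1 % accuracy, γ = 0.0072 kcal mol⁻¹ Å⁻²).
Generalized Born stands in for a grid Poisson–Boltzmann solver: end-point
scoring here ranks alternative models of the *same* solute, a relative
comparison that GB preserves at a small fraction of the cost. The GB
dielectric offset defaults to 0 Å so that an isolated ion reduces exactly
to the Born expression; the AMBER-style 0.09 Å offset is available as a
parameter. Window averages report a block-averaged standard error (five
contiguous blocks by default), which discounts serial correlation that a
per-frame SEM would ignore. Bonded terms are omitted: in single-topology
comparisons they cancel to the extent the internal geometry is preserved,
and the synthetic systems carry no bonded force field.

## Conformational entropy

Backbone torsions α…ζ and the glycosidic χ are extracted per residue
(signed dihedrals in (−180°, 180°], praxeolitic formula), discretized into
rotameric states either by fixed 360/k sectors from a stated origin
(default k = 3, origin 0°, the gauche⁺/trans/gauche⁻ split) or by minima
of a circularly smoothed histogram with a depth criterion (valleys must
descend below 25 % of the tallest mode; otherwise the function warns and
falls back to fixed sectors). The entropy estimate is the
mutual-information expansion truncated at pairwise order with plug-in
probabilities and R = 1.9872 cal mol⁻¹ K⁻¹; MI terms are clamped at zero
against round-off, so MIE2 ≤ S1 always holds, with equality iff the
empirical pairwise distributions factorize. The plug-in estimator biases
entropies low on finite samples; Miller–Madow correction is available as a
flag, off by default. −T·S is reported at 298.15 K unless configured
otherwise. The convergence series (MIE2 over growing leading fractions)
is the practical stationarity diagnostic: report the limiting value only
once it flattens. Higher-order correlation corrections and
Cartesian-coordinate entropies are out of scope.

## Truncation recommendation

Evidence is two per-residue profiles. *Mobility* is the equal-weight mean
of min-max-normalized RMSF and inter-cluster displacement, where each
component is min-shifted and divided by `max(range, 2.0 Å)`: an exactly
constant profile maps to the uninformative 0.5, while a profile whose
total spread is below the floor stays near zero instead of having its
noise stretched to full scale. *Essentiality* flags any residue
participating in (or partnering into) a hydrogen-bond or base-pair contact
with abundance ≥ 50 % (stacking alone does not confer essentiality unless
requested — a stack constrains geometry far less than a persistent
hydrogen bond; binding-site knowledge is deliberately not assumed).

A proposal is the largest terminal run of non-essential residues whose
mean mobility clears `mobility_cut` (default 0.5 — a declared design
default, since no field-standard numeric threshold separates "highly
mobile" from structured); both ends are scanned, proposals are ranked by
removed length, internal excision is never proposed, and the kept region
retains at least `min_length` residues (default 15 nt). The soundness
property — no removed residue is ever essential — is asserted on every
run. Spacer comparison index-aligns a variant against its spacer-free
parent and flags a *structure-altering* spacer when any spacer residue
acquires a high-abundance base-pair contact with a core residue; core
contacts gained or lost are listed after index alignment.

## Synthetic study systems

The fixture generator builds a coarse ssDNA hairpin: ~16 atoms per residue
(phosphate + compressed sugar skeleton, a base-ring hexagon, and
Watson–Crick edge atoms), stem pairs placed with their WC edge atoms
exactly 2.9 Å apart, consecutive stem bases stacked at a 3.4 Å rise, and
loop/tail residues pointing away from the core. Geometric and energetic
choices that make the fixture a meaningful test bed:

* backbone template offsets were optimized once, offline, so that every
  nonbonded and 1-4 pair within a stem — including stacked neighbors and
  the paired strand — stays outside the steep Lennard-Jones wall;
* WC edge atoms carry implicit hydrogens, so they get a reduced LJ radius
  (2.55 Å, well depth 0.8 kcal/mol) and moderate charges (±0.15–0.23 e):
  a formed base pair is then a genuine minimum of the MM-GB/SA score,
  which is what makes end-point model ranking testable;
* the 2.2 Å lateral spacing of edge atoms (wider than chemistry) keeps
  diagonal donor/acceptor combinations outside the hydrogen-bond cutoff,
  so an ideal G·C pair is recovered as exactly its three canonical bonds.

Trajectories are Gaussian-fluctuation constructions, not dynamics: core
atoms get isotropic per-atom jitter (σ_stem, default 0.2 Å), while the
tail moves as a floppy rigid body — a per-frame random swing about the
stem–tail junction (rotation-vector std 25° per component) plus a bulk
translation of amplitude σ_tail (default 2.0 Å), with moves that would
park the tail inside the core redrawn (excluded volume). Independent
per-atom displacements of 2 Å would routinely create sterically impossible
overlaps that explode any Lennard-Jones score; the rigid-body construction
preserves the intended fluctuation amplitudes without them. Discrete
conformers occupy exactly their allotted frame counts (largest-remainder
allocation, contiguous blocks), and a planted contact is present in
exactly its stated fraction of frames. All randomness flows through one
seeded generator; identical seeds reproduce identical coordinates.

What passing tests on these fixtures shows — and does not. They verify
the *analysis machinery*: exact counting, correct superposition and
clustering, recovery of planted structure, closed-form energy terms,
analytic entropies. They do not emulate force-field realism, solvent,
sequence-dependent energetics, kinetic correlation between frames, or the
slow conformational transitions of microsecond trajectories; conclusions
about real aptamers still require real sampling. The boosted-CV fixture
samples exactly from exp(−β[U + ΔV]) with quadratic U and ΔV, for which
the reweighted PMF has a closed-form target; real boost distributions are
only approximately Gaussian per bin.

## Numerical notes and limitations

* Superposition requires ≥ 3 non-collinear fit atoms; degenerate inputs
  raise geometry errors rather than returning ill-conditioned rotations.
* Clustering tie-breaks (equal populations, equal mean RMSD) resolve
  toward lower frame indices, making reports deterministic; permuting
  frames changes labels only up to relabeling.
* Pipeline JSON summaries are byte-deterministic for identical inputs
  (sorted keys, fixed float formatting, wall-clock data only in the log).
* The analysis problem sizes used in tests and in the acceptance script —
  hundreds to a thousand frames, 12–22 residues, 2×10⁵ reweighting
  samples — are the package's desk-scale design point; the O(n²) distance
  matrix is the binding constraint for larger inputs and is mitigated by
  striding, not approximation.
* The NN scorer does not attempt to reproduce any folding server's
  absolute energies (parameter provenance and salt models differ between
  servers and are partly unpublished); its contract is exact consistency
  with its own bundled, inspectable table and correct relative ranking.
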