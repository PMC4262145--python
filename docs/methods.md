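# Methods

## Scope

`rotas` implements a rotamer- and orientation-dependent atomic statistical
potential: training from PDB structures, scoring of candidate models, and
decoy-set evaluation. External preprocessing that full-scale studies apply
to training sets (sequence-identity culling, Asn/Gln/His flip optimization)
and the computation of model-quality scores such as TM-score are outside the
package; quality scores are consumed as inputs.

## Structure model and atom typing

PDB files are parsed with Biopython. Only the first MODEL is read (keeps
NMR ensembles well defined); hydrogens, waters, hetero groups and
nonstandard residues are dropped (nonstandard with a warning — the typing
table is defined only for the 20 standard amino acids). OXT and other
terminal variants are not typed. Alternate locations resolve
deterministically by highest occupancy, then lowest B-factor, then altloc
code. The 167 residue-specific heavy-atom types are enumerated residue by
residue (alphabetical) in a fixed canonical atom order; the enumeration is
checksummed into every potential archive so tables and typing cannot drift
apart silently. Arginine's terminal η atoms are typed as the heavy
nitrogens NH1/NH2. Chain breaks (numbering gap or peptide C–N > 2.5 Å)
split a chain into segments; sequence separation across a break is treated
as infinite.

## Local frames and pair geometry

Every heavy atom *a* carries a right-handed orthonormal frame built from
two in-residue reference atoms: *b*, its canonical bonded predecessor, and
*c*, the predecessor of *b* (for CB: b = CA, c = N; for backbone O: b = C,
c = CA; side-chain atoms use their parent and grandparent along the
covalent tree). Axes: z = unit(a−b), x = the component of (c−b) orthogonal
to z, y = z × x. All references are within the residue, so frames never
depend on neighboring residues and survive chain breaks.

A pair of framed atoms is described by d, (θ, φ) of each atom in the
other's frame (θ azimuth from x in the x–y plane, range [−π, π]; φ
elevation toward z, range [−π/2, π/2]), and ω, the signed angle between the
projections of the two z-axes onto the plane perpendicular to the
interatomic axis. With this construction ω is **swap-symmetric**
(ω(i,j) = ω(j,i), like a bond torsion read from either end); the convention
is fixed here and used identically in training and scoring, which is all
that a statistical potential requires. ω is undefined (and the ω term
skipped) when a z-axis is parallel to the interatomic axis; dihedrals and
frames are undefined for collinear reference geometry, and affected pairs
are skipped with diagnostics.

## Rotameric states

χ angles use the standard four-atom definitions. Each sp3–sp3 dihedral is
binned g+ = [0°, 120°), g− = [−120°, 0°), t = the remaining third; the
bins are half-open on the right (the sources give ranges without a boundary
rule; a fixed convention is required for reproducibility, and boundary
assignment is stable under 1e-12 perturbations). Terminal dihedrals of
Asn, Asp, Gln, Glu, His, Trp, Phe and Tyr are non-rotameric and binned by
sign, 0 counting as positive. Proline's χ1 is binned by sign by default;
the published per-atom table prints three states for Pro, and a
`pro_three_state` switch selects that variant — the discrepancy between the
two sources is deliberately left visible rather than silently resolved.

Each heavy atom is governed by at most two χ angles whose rotating bonds
lie within three bond lengths (the backbone O by {χ1, χ2}); the per-atom
mapping ships as `src/rotas/data/rotamer_scheme.tsv` and is validated
against the typing table at load. States combine by mixed-radix encoding
in χ order (symbol order g+, g−, t and plus, minus). Residues with any
governing χ undefined (missing atoms) contribute no state-conditioned
statistics and are scored from the pooled tables — decoys frequently have
incomplete side chains, and dropping them would bias comparisons. Rotamer
intrinsic energies E(R) are not modeled.

## Distance term

Counts accumulate over all unordered inter-residue heavy-atom pairs below
15 Å in 0.5 Å bins (no sequence-separation filter for the distance term;
same-residue pairs excluded). The DFIRE reference gives

    E(i,j,d) = -kT ln[ N_obs(i,j,d) / ((d/d_cut)^1.61 N_obs(i,j,d_cut)) ]

evaluated at bin centers with d_cut the 14.5–15 Å bin, which is zero by
construction. Unobserved bins of observed pairs get a finite +10 kT cap so
clash-containing decoys still score; pairs with no cutoff-bin counts are
flagged unusable and score zero with a warning. kT = 1 throughout: scores
are dimensionless and extensive (no length normalization), so only models
of the same target are compared.

## Angular terms

For every eligible pair (2 ≤ d < 15 Å, separation ≥ 6 residues within a
segment, cross-chain/cross-break always eligible, both frames defined) both
ordered directions are recorded: (θ<sub>i</sub>, φ<sub>i</sub>, ω) under
the type key (t<sub>i</sub>, t<sub>j</sub>) conditioned on R<sub>i</sub>,
and symmetrically for j. Densities are von Mises kernel estimates with
κ = 8.21 — the concentration equivalent to a normal kernel of σ = π/9 via
σ² ≈ 1/κ — evaluated on a π/9 grid (19 points on [−π, π], wraparound
endpoints sharing one value; 10 points on [−π/2, π/2]) and renormalized by
trapezoidal quadrature on their grid, so every stored density integrates
to 1 ± 1e-6. Kernel sums are accumulated streamingly per
(type<sub>i</sub>, type<sub>j</sub>, distance bin, state); the pooled
record is the sum over states, so pooled and state-conditioned statistics
agree by construction. Storage is sparse: only observed keys exist, and a
missing state at scoring time falls back to the pooled grid — equivalent
to the sparse-state correction at N = 0.

The sparse-state correction mixes state and pooled densities with weight
w = σN/(1+σN), σ = 1/100, which satisfies the defining property of equal
weights at N = 1/σ = 100 and approaches pure state statistics as N → ∞.
The expected (reference) density is that of a uniformly random relative
orientation smoothed with the same kernel: uniform 1/(2π) for θ and ω
(circular convolution of a uniform is uniform), and the cos φ area prior
smoothed numerically for φ, renormalized on the grid (there is no closed
form for that integral; a 2001-point trapezoid rule computes it to well
below the 1e-6 normalization tolerance). Energies are −kT ln(P̃_obs/P_exp)
per term. The joint ω dependence on both endpoint states uses the
conditional-independence factorization
P(ω|d,R<sub>i</sub>,R<sub>j</sub>) ≈
P(ω|d,R<sub>i</sub>)P(ω|d,R<sub>j</sub>)/P(ω|d), i.e.
E(ω|d,R<sub>i</sub>) + E(ω|d,R<sub>j</sub>) − E(ω|d); the joint over state
pairs would be far too sparse to estimate.

## Scoring

The total energy of a model sums, over all heavy-atom pairs within the
10 Å interaction cutoff, the distance term plus (for pairs meeting the
training-time separation and frame requirements — the same filters, for
train/score consistency) the five angular terms, with linear interpolation
on the angle grids between grid points. Neighbor search uses a k-d tree;
its correctness is defined solely by the brute-force O(n²) oracle in the
test suite. Scoring is deterministic and invariant under rigid motion of
the model (tested to 1e-6). The cutoff is exposed as a parameter so
cutoff-sweep experiments can be reproduced; energies at cutoff c₁ < c₂
differ exactly by the contributions of pairs in (c₁, c₂].

## Evaluation metrics

Native rank uses pessimistic tie handling (tied decoys rank ahead of the
native). The Z-score uses the population standard deviation over decoys,
native excluded. logP_Bk = ln(min_{i≤k} R_i / n) where R_i is the quality
rank (1 = best, ties by minimum rank) of the i-th lowest-energy of n
decoys; natural log by default with a log10 switch, and the native is
excluded from n — both conventions are switches because the printed
definition leaves them open. logP_Bk is monotone non-increasing in k.
Pearson r and Kendall τ-b come from scipy; correlations are reported both
with and without the native (quality 1). The ROC AUC treats lower energy
as more positive (near-native = quality > 0.5), computed as the normalized
Mann–Whitney U with ties counting 1/2, and requires more than 10 positives
and at least one negative per target; cross-checked against scikit-learn
in tests. Paired t-tests (scipy) compare per-target AUC lists and signal
degeneracy on zero-variance differences. `evaluate_suite` aggregates all
metrics per decoy set and overall; undefined metrics are reported as NaN
with a skip reason, never silently dropped.

## Synthetic fixtures

Chains are built by sequential internal-to-Cartesian (NeRF) placement from
a fixed ideal-geometry table (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å,
C=O 1.231 Å, standard side-chain lengths and angles per residue z-matrix);
φ/ψ/peptide-ω and all χ are controllable, and rebuilt χ angles round-trip
to 1e-6° because χ-defining atoms are placed with that very dihedral.
Branch atoms use fixed ±120°/180° offsets; one consistent Cα hand is used
for all fixtures. Ring closures are approximate (rings are placed by
z-matrix, not refined), which is irrelevant to the statistics tested.
Decoys add independent Gaussian coordinate noise per atom; the noise level
σ maps to a quality surrogate 1/(1+σ) in (0, 1] that is used only in
tests — real evaluation consumes externally computed TM-scores. Planted
training sets position a single-residue second chain so a designated atom
pair sits at a controlled distance (default 5.25 Å, a distance-bin center:
planting on a bin boundary would scatter samples across two bins through
rounding) with θ<sub>i</sub> drawn tightly around a state-dependent mode,
exploiting the cross-chain bypass of the sequence-separation filter.

What the fixtures do not emulate: real packing, solvation, secondary
structure diversity, missing atoms/altlocs of experimental files, and
realistic decoy ensembles. Passing tests therefore demonstrate the
correctness of the machinery (counting, estimation, assembly, metrics) and
the recoverability of rotamer-conditioned angular preferences from data
that contain them — not the field performance of the potential, which
depends on training-set scale.

## Problem sizes

The shipped tests and the acceptance script train on 6–20 eleven-residue
helices, 150 planted two-chain structures, and 5 evaluation targets with
16 decoys each at noise levels 0.2–1.2 Å — sizes chosen so the whole
pipeline, including brute-force oracles, runs comfortably on one CPU while
every statistical assertion still has adequate power.

## Potential archive format

`save`/`load` use a NumPy `.npz` container: dense distance-energy and
usability arrays, the sparse angular tables as flat key/value arrays, and
a JSON metadata entry (format version, builder configuration, typing-table
checksum, training manifest, sample counts). Loading validates the format
version and the typing checksum; truncated or foreign files raise a
format error. Round-trips are bit-exact.

## Known limitations

* The local-frame reference-atom table is this package's own deterministic
  construction from covalent topology; other orientation-dependent
  potentials choose different (unpublished) frames, so trained tables are
  self-consistent but not interchangeable with theirs.
* Alternative distance reference states (beyond DFIRE) are out of scope;
  the builder's reference is pluggable in principle but only DFIRE ships.
* Rotamer intrinsic energies and evolutionary terms are not modeled.
* Proline's state alphabet is source-ambiguous (see above); both variants
  are available, and tables record which was used.
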