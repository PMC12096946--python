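# Methods

This note documents the models, conventions and numerical choices
behind `ccdimer`, in the order an analysis runs: structure model,
synthetic generators, secondary structure, contacts, geometry,
surfaces, ensemble statistics, and variant reports.

## Structure model and I/O

An ensemble is an ordered list of models over one topology; topology
identity (chains, author residue numbers, insertion codes, residue
names, atom-name sequences) is enforced at load and construction time,
and the first differing residue is named in the error. Author
numbering is authoritative throughout (PALB2 6–42, BRCA1 1380s–1420s);
nothing is renumbered. Waters and hetero residues are dropped at load.
Altloc groups keep the highest-occupancy conformer (ties → altloc "A").
Blank element columns are inferred from atom names by the PDB v3
convention. Hydrogens are kept and flagged; all heavy-atom analyses
filter on the element. PDB output goes through gemmi's fixed-width
writer, so coordinates round-trip to 10⁻³ Å. Binary trajectory formats
(XTC/DCD) are out of scope; convert frames to a multi-MODEL PDB (e.g.
`mdconvert -o frames.pdb traj.xtc -t top.pdb`) or a directory of
per-frame PDBs read with `read_frames`.

## Synthetic coiled coils

`build_coiled_coil` places each chain as an ideal α-helix
(φ = −57°, ψ = −47°, ideal bond geometry via torsion-chain extension)
and maps it onto a left-handed superhelical path with radius *R₀*
(default 4.9 Å) and pitch *P* (default 145 Å). The z coordinate is
reinterpreted as arclength along the curved axis so the local rise per
residue survives the mapping; consecutive CA distances stay within
3.7–3.9 Å. The default pitch puts the inter-helix packing angle at
2·atan(2πR₀/P) ≈ 24°, the value typical of short antiparallel coiled
coils. Before the mapping, each chain is rotated about its own axis so
the mean azimuth of the interface side chains points at the partner;
which heptad positions form the interface is a parameter
(`interface_positions`, default the classic a/d core). The bundled
PALB2 sequence uses an a/e ladder — L17/L24/T31 at *a* and L21/Y28/L35
at *e* — which reproduces the published interface signatures: the
central L24–L24′ leucine pair at Cδ–Cδ ≈ 4 Å and ≥80% of ladder
residues in 7 Å inter-chain contact. Antiparallel builds flip chain B
about x and shift it axially so chain-A index *i* faces chain-B index
*S − i*; `antiparallel_z_shift` converts a register sum *S* into the
shift. The heterodimer register (S = 49 between the PALB2 chain and the
synthetic BRCA1-like chain) places Tyr28 against the partner's central
leucines, reproducing the CH–π contact onto the Tyr28 ring face, and
places Lys18 near the partner's C-terminal acidic patch.

The bundled partner sequence is **synthetic**: the real BRCA1
coiled-coil sequence is not distributed with the package. The stand-in
carries the published PALB2-facing anchor residues (D1381, S1387,
D1390, L1392, M1400, L1404, L1407, M1411, L1414, L1418, D1419) at
their real positions, 4 positive and 7 negative residues (net −3,
acidic C-terminus), and leucine-zipper positions elsewhere. Analyses
of the real complex should load the deposited structures instead.

Side chains are built from internal-coordinate templates
(Engh–Huber-style ideal bond lengths and angles) with a compact
rotamer table of most-common χ sets per residue; a χ₁ grid scan backs
the table up. `mutate_residue` keeps the backbone fixed, rebuilds the
side chain, and picks the candidate with the fewest heavy-atom
clashes (< 2.4 Å) against the rest of the structure, returning a
best-effort placement (logged) when none is clash-free. This is a
deliberately light replacement for a full rotamer library: it is
sufficient for contact-level analyses, which is what the package
computes; it does not produce energy-minimized side chains.

`perturb_ensemble` displaces each residue rigidly by an isotropic
Gaussian 3-vector with that residue's σ (per-atom mode behind a flag).
Rigid per-residue displacement keeps side-chain geometry intact so
contact networks degrade smoothly with σ, and gives the exact
expectation RMSF = σ√3 used in parameter-recovery tests. Seeds are
mandatory; there is no hidden global RNG.

`emulate_unfolding` rebuilds a window of residues with random
extended-coil dihedrals (φ ∈ [−160°, −60°], ψ ∈ [100°, 170°]) while
preserving ideal bond geometry; model *k* randomizes a window growing
from the start residue toward the C-terminus, and everything
downstream of the window rides rigidly on the last rebuilt frame. The
result is a progressive unfolding ensemble with a monotone helicity
decay — the phenotype of a helix-breaking substitution.

## Secondary structure

Backbone hydrogen bonds use the Kabsch–Sander electrostatic model,
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, with a
bond called at E < −0.5. When files carry no protons the amide H is
built at 1.01 Å along the bisector of the CA→N and C(prev)→N
directions; proline never donates. Sequence-adjacent residues
(|i−j| < 2) are excluded. A residue is labelled H when two consecutive
i → i+4 turns cover it (the minimal DSSP α rule); 3₁₀ and π helices
collapse into coil because the downstream quantity is percentage
α-helicity only. Chain breaks (CA–CA > 4.5 Å) terminate bonding
patterns, and chains shorter than five residues are all coil. On ideal
fixtures the assignment reproduces the (N−4) hydrogen-bond ladder and
agrees with mdtraj's DSSP implementation on ≥90% of residues; the
helicity denominator is every labelled residue in the selection
(configurable by selecting residue ranges).

## Contacts

Contacts are heavy-atom pairs within a cutoff, enumerated with a
k-d tree and verified against a brute-force O(N²) oracle in the test
suite. Intra-protomer mode excludes pairs within one residue and
within |i−j| < 2 along the chain so counts measure tertiary packing
(the exclusion width is a parameter). Two "contact" units are
reported: distinct residue pairs (interface totals) and atom pairs
(trajectory series); both are monotone in the cutoff and invariant
under rigid motion and chain relabeling. Default cutoffs: 7 Å for
packing counts, 10 Å for native-contact retention at mutation sites.

Classification is rule-ordered: salt bridge (Lys NZ / Arg NH*, NE /
N-terminal N against Asp OD* / Glu OE* / C-terminal O(XT), ≤ 4.0 Å),
then hydrogen bond (N/O donor–acceptor ≤ 3.5 Å with D–H…A ≥ 120° when
a proton is present or can be built; for rotatable side-chain donors
without a proton the antecedent–donor–acceptor angle must exceed 90°),
then hydrophobic (both atoms apolar side-chain C/S, ≤ 4.5 Å), then
generic van der Waals (≤ 4.5 Å). The hydrogen-bond thresholds are
standard geometric criteria; the salt-bridge distance is the common
4 Å convention.

Native-contact retention defines the native set as all qualifying
pairs in a reference model restricted to two selections and reports
the per-model fraction still within the cutoff. Salt-bridge occupancy
is the fraction of models in which a residue pair forms any
salt-bridge contact.

Replicate statistics follow simulation practice: the per-replicate
value is the mean over frames; groups are compared with a two-sample
pooled-variance Student t (df = n₁+n₂−2), one-tailed in the direction
of the observed difference, so identical groups give t = 0, p = 0.5;
the normalized value is mean(mut)/mean(wt). Degenerate zero-variance
groups give p = 0 when the means differ.

## Geometry

Helix axes are fitted through local helical centers (mean of four
consecutive CA), taking the principal direction oriented N→C;
fit RMSD is reported and ≥7 consecutive residues are required. The
crossing angle is the angle between two N→C directions; orientation is
antiparallel above 90°, and the reported packing angle is
min(θ, 180°−θ) so values are comparable across sign conventions (the
raw θ is also returned).

Ring geometry fits each aromatic plane by least squares, folds the
normal–normal angle into [0°, 90°], and reports the C_ζ–C_ζ distance
for Tyr/Phe (centroid distance otherwise, e.g. His). Classes:
parallel below 30°, edge-to-face above 60°, both gated by a centroid
distance ≤ 7.5 Å; the thresholds are standard π-stacking values and
are parameters — the classification logic, not the numbers, is the
load-bearing part. Met–aromatic interactions are called when the Met
SD sits within 6 Å of a ring centroid; CH–π when an apolar side-chain
carbon lies within 4.5 Å of the centroid and within 40° of the ring
normal (over the face, not the edge).

## Surfaces and charge

SASA is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points; doubling changes totals by <1%), Bondi radii, and
a 1.4 Å probe, over heavy atoms only. Buried surface area is the
both-sides convention BSA = SASA(A) + SASA(B) − SASA(AB) with **no
division by two** — stated prominently because published interface
areas are convention-sensitive (a one-sided number is half of ours).
For multi-model ensembles the model-1 value and the ensemble
mean ± s.d. are reported. The axial charge profile bins formal
side-chain charges (K/R +1, D/E −1, H 0) by CA projection onto a
fitted helix axis; terminal backbone charges are excluded by default
because the analyzed constructs are internal fragments.

## Ensemble statistics

Superposition is the Kabsch least-squares fit (proper rotation
enforced). RMSF superposes all models onto an iteratively refined mean
structure (three rounds, configurable — convergence at these sizes is
well inside numerical noise) and reports per-atom fluctuations about
that mean; the default selection is all CA atoms, matching the Cα RMSF
convention. Least-squares superposition absorbs six degrees of freedom
of the noise, so recovered RMSF underestimates the generator's σ√3 by
roughly √(1 − 2/N) for N rigidly moving residues (≈1.4% at N = 74);
recovery tests use a 5% tolerance, which covers this bias plus
sampling noise at the ensemble sizes used. `replicate_summary` reports
per-replicate means, the group mean, and the sample (n−1) standard
deviation of replicate means.

## Variant reports

`build_report` compares wild-type and mutant replicate ensembles per
context. Metrics: backbone hydrogen bonds and helicity (protomer and
homodimer), inter- and intra-protomer atom contacts at 7 Å
(homodimer), and mutation-site contacts to the partner chain at 10 Å
(heterodimer). One headline metric drives the call per context —
backbone H-bonds (protomer), inter-protomer contacts (homodimer), site
contacts (heterodimer); all metrics and p-values are stored in the
report. Calls use normalized-value bands at α = 0.05: reduced ≤ 0.8,
slightly enhanced in [1.05, 1.2), enhanced ≥ 1.2, otherwise no effect.
The source study reports calls qualitatively; these thresholds encode
one consistent reading of its normalized figures (≈50% heterodimer
contact loss for the most damaging variant, ≈30% for intermediate
ones, modest gains for the enhancing ones) and are configurable.

## The synthetic phenotype suite

The six-variant suite (K18R, L24S, Y28C, T31I, R37H, L35P) generates
wild-type and mutant replicate ensembles in all three contexts with
the variant's described phenotype built in as ground truth:

* destabilized protomers (Y28C, L35P) are progressive-unfolding
  ensembles (windows opening at residues 22 and 24);
* destabilized homodimers (Y28C, L35P) additionally sample an open,
  chain-separated state in 35% of frames on top of the mutated
  interface;
* heterodimer effects are emulated as per-frame engagement of the
  mutation site with the partner chain: the wild type is engaged in
  60% of frames, and each mutant's engaged-frame count is calibrated —
  against noise-averaged pilot estimates of the per-frame site count,
  correcting for the mutation's own side-chain size change — to realize
  the described effect size on the wt-normalized site-contact ratio
  (0.50 L35P, 0.70 L24S, 0.45 Y28C, 1.12 K18R and T31I, 1.30 R37H).
  Disengaged frames translate the partner chain 30 Å away so they
  contribute exactly zero site contacts and the calibration is exact
  in expectation.

Defaults: background fluctuation σ = 0.25 Å, 40 frames per replicate,
3 replicates per group. These sizes keep the full suite within a few
minutes on one CPU while the replicate-level standard errors stay well
inside the call bands.

**What passing does and does not show.** The suite tests that the
measurement chain — mutation building, contact and hydrogen-bond
counting, normalization, replicate statistics, and call logic —
recovers an impact pattern that is present in the ensembles by
construction. It does not re-derive the phenotypes from physics:
Gaussian-perturbed ideal helices have no force field, no solvent, no
kinetics, and their absolute counts (e.g. the synthetic dimer's
≈1500 Å² buried surface) are smaller than those of the experimental
ensembles. Quantities that require microsecond sampling (absolute
helicity decays, salt-bridge occupancy shifts in the real complex) are
covered qualitatively, not numerically.

## Degenerate inputs and tie-breaks

Empty selections are allowed in `select` but rejected where a
denominator needs them (helicity, native sets, SASA). Colinear
reference atoms in internal-coordinate placement fall back to an
arbitrary perpendicular. Zero pooled variance yields p ∈ {0.5, 0} as
described. Canonical unordered storage of contact pairs (sorted
addresses) makes counts independent of enumeration order. All
generator outputs validate against the structure model and round-trip
through PDB.

## Known limitations

* Side-chain placement is rotamer-table quality; χ angles are not
  refined against an energy function, so atom-level contact lists on
  synthetic structures carry placement noise of a few contacts.
* The secondary-structure assigner distinguishes only H vs not-H.
* The BRCA1-like partner chain is a synthetic stand-in (see above).
* Ring classification thresholds are conventions, not fitted values.
* No binary trajectory readers; frames must be provided as PDB.
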