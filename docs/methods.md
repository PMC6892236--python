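# Methods

This note documents the models, numerical choices and limitations behind
`fragswap`. It describes what the code computes; every number quoted here
is one the test suite or `scripts/acceptance.py` computes at run time.

## The design problem

Given two homologous enzymes — in the reference system a mesophilic GH10
xylanase (XylE) and a thermophilic homolog (XYL10C) sharing ~53%
sequence identity and a common (α/β)₈-barrel fold — fragment replacement
builds hybrids by substituting contiguous peptide segments of the
recipient with the donor's aligned counterparts. Two hard rules define a
swap-compatible partition of the aligned pair:

1. **Structure preservation.** A fragment boundary may fall only where
   both parents are coil, so no helix or strand run is interrupted on
   either parent.
2. **Internal length bound.** Every fragment except the N- and
   C-terminal ones spans at most `max_internal_len` residues on *both*
   parents (default 19, a strict reading of "shorter than 20"; gapped
   alignments can make counterpart lengths differ, hence the two-sided
   check).

A third, artifact-level rule — `min_fragment_len`, default 5 — excludes
degenerate one-residue "fragments", which would be point mutations
rather than segment swaps. It is configurable down to 1.

## Alignment and secondary structure

Parents are aligned globally (Needleman–Wunsch with affine gaps) through
Biopython's `PairwiseAligner`: BLOSUM62, gap open 10, extend 0.5 —
common expert defaults for ~50%-identity proteins. Determinism comes
from taking the aligner's first-ranked traceback for fixed parameters;
optimality is enforced by tests against an exhaustive small-input oracle
and by recomputing the score from the emitted column list. Identity is
counted over aligned residue pairs only (identical pairs / aligned
pairs × 100).

Secondary structure is either supplied per residue as an H/E/C string —
the preferred path when a reference assignment exists — or derived from
backbone dihedrals: a residue is helical when φ ∈ [−100°, −30°] and
ψ ∈ [−80°, −5°], extended when φ ∈ [−180°, −60°] and ψ ∈ [60°, 180°] ∪
[−180°, −150°]; runs shorter than 4 (helix) or 3 (strand) smooth to
coil, as do residues missing backbone atoms or a full dihedral pair
(chain termini). This is a deliberately simple dihedral-window proxy,
not a hydrogen-bond-energy assignment (no DSSP re-implementation), and
true structural superposition is out of scope: an SS-annotated sequence
alignment stands in for a structure alignment.

## Demarcation solver

Candidate junctions are alignment columns c such that the window
c−w .. c+1+w (w = `eligibility_window`, default 1) is gap-free on both
parents, both residues at c are coil, and the cut splits no H/E run.
Cut selection is a dynamic program over candidates with two objectives:

* `max_internal_count` — maximize the number of fragments subject to
  the length rules (ties broken toward the leftmost cut columns);
* `("target_count", k)` — exactly k fragments if feasible, preferring
  the most even internal lengths (minimal sum of squared fragment
  lengths over both parents), then leftmost cuts. Infeasible targets
  raise an error reporting the maximum achievable count.

Schemes tile both parents completely; where a real campaign might leave
linkers unassigned, this artifact treats complete tiling as part of the
contract and `validate_scheme` re-checks every invariant independently.

## Chimeras, codons, primers

A fragment's donor interval is alignment-mediated: the donor residues
aligned to the recipient interval's columns, extended through interior
gaps, so swaps may change length under indels. Names normalize fragment
order ascending (`XylE-M3/M6`, never `M6/M3`) and round-trip through a
parser. Reverse translation inherits each residue's codon from its
provenance parent's CDS when given (after verifying the CDS translates
to the parent protein); without a CDS it uses a deterministic canonical
codon — the alphabetically first synonymous codon of the named NCBI
table, since codon *tables* carry no organism frequencies.

Overlap-extension primers span each junction with `min_flank` nt
(default 15) on both sides, growing symmetrically to at most 40 nt until
forward and reverse melting temperatures enter the target band;
unreachable bands yield flagged best-effort primers. Tm is computed by
the Wallace 2+4 rule or by unified nearest-neighbor thermodynamics
(SantaLucia 1998 parameters) at the 1 M Na⁺ reference with no salt
correction, 25 nM per strand (non-self-complementary duplex, effective
concentration 12.5 nM): Tm = 1000·ΔH / (ΔS + R ln C) − 273.15. The test
suite cross-checks this against Biopython's independent implementation.

## Enzymology

* **Units.** 1 U = 1 µmol xylose equivalents released per minute;
  specific activity = µmol / min / mg enzyme. Assay conditions (pH,
  temperature) are metadata recorded verbatim, never inferred.
* **Michaelis–Menten.** The default route is Lineweaver–Burk (ordinary
  least squares of 1/v on 1/[S]; K_m = slope/intercept,
  V_max = 1/intercept), mirroring how such kinetics are conventionally
  reported; because double-reciprocal regression is statistically
  fragile, a direct nonlinear fit of v = V_max[S]/(K_m+[S]) is provided
  and cross-checked (both agree to ≥ 6 significant digits on noise-free
  data). The nonlinear fit weights residuals by the rate (relative least
  squares), the correct objective when assay noise scales with the
  signal (constant CV). Saturated data (K_m → 0) warn rather than fail.
* **Turnover.** k_cat = V_max · M / 60 with M the mature-protein mass in
  kDa — a user input, since glycosylation makes apparent masses exceed
  theoretical ones; absent a value it is estimated from sequence at
  110 Da per residue and the choice logged. k_cat/K_m is reported in
  mL s⁻¹ mg⁻¹ because the polymeric substrate is quantified by mass.
* **T50.** Residual activity after a fixed pre-incubation is modeled as
  a two-parameter logistic on the percent scale,
  R(T) = 100 / (1 + exp((T − T50)/s)). T50 is defined operationally
  (half-maximal retention), so a model-free fallback — linear
  interpolation of the 50% crossing — is available by flag. A fitted
  T50 outside the assayed range or a curve that never crosses 50% is an
  error, not an extrapolation.
* **Half-life.** First-order inactivation, ln R = ln R₀ − k t,
  t₁/₂ = ln 2 / k; non-decaying data warn and report an infinite
  half-life sentinel.
* **Degree of synergy.** DS(t) = Y₁₊₂ / (Y₁ + Y₂) on the raw arm values
  by default — the formula as defined carries no control term — with an
  optional control-subtraction flag since timecourses usually include a
  no-enzyme arm. Points with a non-positive denominator are skipped with
  a warning. DS is scale-invariant by construction.
* Report rounding is 2–3 significant figures in CLI output; full
  precision is kept internally.

The stored characterization table for the XylE/XYL10C family
(`fragswap.datasets`) contains two internal inconsistencies that the
toolkit surfaces rather than corrects: the XylE-M3 row's efficiency
column (860 / 0.61 ≈ 1410, printed 1340) and the XYL10C-M6 relative
efficiency (printed 940 / 4400 ≈ 21%, quoted as 19%). Recomputed values
are always reported as recomputed. Calorimetric T_m values are stored
measurements only and are never computed.

## Hydrogen-bond occupancy

A donor–acceptor pair is bonded in a frame when the heavy-atom distance
is ≤ 3.5 Å and the donor–hydrogen–acceptor angle is ≥ 120° — the common
geometric convention, exposed as parameters since published analyses
rarely state theirs. Hydrogens are assigned to the nearest catalogued
donor heavy atom of the same residue within 1.25 Å; frames with no
hydrogens at all degrade to the distance criterion alone, flagged in the
output (crystallographic inputs often lack hydrogens). Occupancy is the
percentage of window frames in which the pair is bonded; windows are
frame-index ranges (e.g. the trailing 25% of a trajectory, after
equilibration). Atom labels use the `RES_seq@atom` grammar (`E_153@OE2`)
with 1-based mature-sequence numbering.

## Synthetic data and what passing tests show

Generators are deterministic under an integer seed (NumPy `Generator`)
and return the planted truth alongside the data; truth is read only by
tests, never by library code. Conditions emulate the reference study:
parent pairs at 47% substitution (≈ 53% alignment identity) over a
134-residue layout with nine interior coil gaps (so a ten-fragment
scheme is feasible); kinetics on a six-point 0.5–10 mg/mL substrate grid
with multiplicative Gaussian noise (CV-parameterized), planted at the
wild-type (0.75, 680) and best-single-swap (0.42, 1160) parameter sets;
logistic T50 curves at 30–80 °C with planted midpoints 66.5–71.2 °C;
first-order decays with half-lives 1.2–2.3 h; synergy timecourses
parameterized directly by a target DS(t) so the analysis has a
closed-form oracle; trajectories of 20 frames with hydrogen bonds
planted on explicit frame schedules among far-spaced decoys.

What the fixtures do **not** emulate: real substitution processes (rate
heterogeneity, conservation structure), force-field-realistic geometry
or thermal motion, instrument drift or heteroscedasticity beyond the
stated noise models, and inhibition or substrate-depletion effects in
the assays. Passing tests therefore demonstrate correctness of the
algorithms and estimators under the stated models — recovery of planted
parameters, agreement with brute-force oracles, invariances — not
field performance on laboratory data.

Problem sizes used by the checks (chosen to keep the oracles exact):
exhaustive demarcation equivalence on alignments ≤ 60 columns;
noisy-recovery studies over 200 seeded replicates at 5% CV; alignment
optimality against full enumeration for sequences ≤ 6 residues;
20-frame trajectories for occupancy.

## Known limitations

* Sequence alignment + SS annotation approximates a structure
  alignment; for exact reproduction of a published fragment scheme,
  supply the reference SS strings (and, if needed, the author-numbering
  offset — e.g. when a mature protein's first residue is not residue 1
  of the deposited sequence).
* The demarcation objective is explicit configuration; a manually
  curated scheme may differ from both built-in objectives while
  satisfying the same two hard rules.
* Primer design checks only the two cloning sites (EcoRI/NotI, as a
  warning) and assumes repeat-free constructs; no secondary-structure or
  cross-dimer screening.
* Insertion codes in PDB inputs are rejected rather than resolved, and
  mmCIF / binary trajectory formats are unsupported.
* The multi-frame occupancy statistic is post-processing only; no
  simulation, energy-based bond definition, or binding-energy analysis
  is included.
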