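# fragswap

Fragment-replacement design and characterization toolkit for hybrid
enzymes.

Fragment replacement is a rational protein-engineering strategy for a
pair of homologous enzymes — here a mesophilic GH10 endo-xylanase (XylE)
and a thermophilic homolog (XYL10C) at ~53% sequence identity: the
aligned parents are partitioned into swap-compatible peptide fragments,
and hybrids are built by substituting one or more fragments of the
recipient with the donor's structurally aligned counterparts. `fragswap`
covers the desk side of such a campaign end to end:

* **Demarcation** — cut sites are restricted to coil–coil alignment
  columns so that no fragment boundary interrupts a helix or strand on
  either parent, and every internal fragment is kept shorter than 20
  residues on both parents. Within those hard constraints a dynamic
  program either maximizes the fragment count or hits a requested count
  exactly (e.g. the ten-fragment scheme of the XylE/XYL10C system).
* **Chimera design** — single and combinatorial swaps in both
  directions, canonical names (`XylE-M3/M6`), codon-faithful reverse
  translation from parent CDSs, and junction-spanning primer pairs for
  two-step overlap-extension PCR (Wallace or SantaLucia nearest-neighbor
  melting temperatures).
* **Enzymology** — specific activity (1 U = 1 µmol xylose equivalents
  min⁻¹), Michaelis–Menten fits by Lineweaver–Burk regression
  (1/v = Km/Vmax · 1/[S] + 1/Vmax) or weighted nonlinear least squares,
  k_cat = Vmax·M/60 and catalytic efficiency k_cat/K_m (mL s⁻¹ mg⁻¹ for a
  mass-quantified polymeric substrate), fold-change summaries, logistic
  T50 fits, first-order half-lives t_1/2 = ln 2 / k, and the degree of
  synergy of xylanase + cellulase co-hydrolysis,
  DS(t) = Y_{1+2} / (Y_1 + Y_2).
* **Hydrogen-bond occupancy** — geometric detection (donor–acceptor
  ≤ 3.5 Å, D–H···A ≥ 120°) over multi-model coordinate frames and the
  percentage of analysis-window frames in which each pair is bonded.
* **Fixtures** — seeded generators for every input: parent pairs with a
  designed secondary-structure layout, ideal-geometry backbones,
  kinetics/thermal/synergy tables with planted parameters, and
  trajectories with scheduled hydrogen bonds.

## Worked example

Generate a synthetic parent pair in the study regime (53% identity,
ten-fragment-feasible secondary-structure layout), demarcate it, and
build the seven M3/M6/M9 combination hybrids:

```sh
$ fragswap simulate --kind parent_pair --seed 7 -o pair
$ fragswap demarcate --parents pair/a.fasta pair/b.fasta \
    --ss pair/parentA.ss pair/parentB.ss --objective target:10 -o scheme.tsv
identity 53.0%; 10 fragments -> scheme.tsv
$ fragswap chimera --scheme scheme.tsv --parents pair/a.fasta pair/b.fasta \
    --ss pair/parentA.ss pair/parentB.ss --recipient parentA \
    --combinations M3,M6,M9 -o hybrids.fasta
7 construct(s) -> hybrids.fasta
```

The alignment identity matches the parent pair's design, the scheme
tiles both parents into fragments M1..M10 whose internal members are
≤ 19 residues on each parent, and the seven constructs are every
non-empty subset of {M3, M6, M9} swapped into parent A.

Fit a kinetics table with a planted wild-type parameter set
(K_m = 0.75 mg/mL, V_max = 680 µmol/min/mg) and derive the turnover
columns with a 37.9 kDa mature mass:

```sh
$ fragswap simulate --kind kinetics --seed 7 -o sim
$ fragswap kinetics --in sim/kinetics.csv --mw-kda 37.9 -o row.tsv
Km=0.75 mg/mL, Vmax=680 umol/min/mg (lineweaver_burk) -> row.tsv
$ cat row.tsv
quantity	value	unit
Km	0.75	mg/mL
Vmax	680	umol/min/mg
kcat	429.5	/s
kcat_over_Km	572.7	mL/s/mg
r_squared	1.000000	-
```

On noise-free data the double-reciprocal fit returns the planted
parameters exactly; k_cat = 680 × 37.9 / 60 ≈ 430 s⁻¹ and
k_cat/K_m ≈ 570 mL s⁻¹ mg⁻¹ are the wild-type XylE characterization
values. The other subcommands (`thermal`, `synergy`, `primers`,
`hbond`) follow the same pattern; `fragswap <cmd> --help` documents the
input headers.

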