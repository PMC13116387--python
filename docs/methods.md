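# Methods

## Compound handling and deduplication

A library record is (identifier, name, SMILES, source). Validity and
uniqueness are decided on a canonical isomeric SMILES key (RDKit
canonicalization, stereochemistry preserved): two spellings of the same
molecule collapse to one key, while isomeric and flat spellings of a
stereocenter remain distinct. Names are deliberately not used for
deduplication — compound names in drug-signature databases are unreliable.
The first occurrence of a structure wins; every removed record is logged
with exactly one reason code, with precedence missing-SMILES →
unparseable-SMILES → duplicate-structure, so the kept + rejected partition
always accounts for the input. Salt stripping, tautomer canonicalization
and other standardization pipelines are out of scope.

## Descriptors

All descriptors come from RDKit on the hydrogen-implicit canonical
structure: molecular weight, Wildman–Crippen logP and molar refractivity
(atom-contribution methods), H-bond donor/acceptor counts, rotatable bonds,
TPSA, total atom count including hydrogens, aromatic ring count, the
Bickerton QED desirability composite on [0, 1], and the
Ertl–Schuffenhauer fragment-contribution synthetic-accessibility score on
its raw 1 (easiest) to 10 (hardest) scale. Structural alerts use RDKit's
built-in, versioned PAINS (A + B + C families) and BRENK SMARTS catalogs;
shipping the catalogs through the library rather than as copied data files
keeps them tied to the RDKit release and avoids drift. Descriptors are
deterministic functions of the structure key, so explicit-hydrogen input
spellings give identical results.

## Seven-component scoring

Each dimension must land on [0, 1]; the concrete maps chosen here are:

| component | map | rationale |
|---|---|---|
| Lipinski | fraction of 4 criteria passed (MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10) | graded values are more informative than a pass/fail bit and reduce ties |
| Veber | fraction of 2 (RotB ≤ 10, TPSA ≤ 140 Å²) | same |
| Ghose | fraction of 4 (MW 160–480, logP −0.4–5.6, MR 40–130, atoms 20–70) | same |
| QED | raw value | already a [0, 1] desirability score |
| SA | (10 − SA)/9, clamped with a warning outside [1, 10] | orients the scale so higher = more synthesizable |
| ADMET | fraction of 6 property windows (MW 150–500, logP −0.7–5.0, TPSA ≤ 140, RotB ≤ 10, HBD ≤ 5, aromatic rings ≤ 4) | a transparent rule-based stand-in for ADMET liability; the six windows are conventional oral-drug property ranges |
| alerts | max(0, 1 − 0.5·n) | simplest monotone penalty; one alert halves the component, two zero it |

Weights (0.15, 0.10, 0.10, 0.20, 0.15, 0.20, 0.10) must sum to 1 within
1e-12 and are validated before aggregation; the total is accumulated with
compensated summation so stored scorecards re-derive their own total to
1e-12. Grade bands are left-closed at 0.85/0.70/0.55/0.40 — a score of
exactly 0.85 is an A. Library percentages round half-up to one decimal
(banker's rounding would not reproduce conventional reporting); means and
medians are reported to three decimals.

## Docking geometry

PDB text is parsed by fixed columns. Alternate locations collapse to one
atom per (chain, residue, atom name): a blank altloc wins, otherwise the
highest occupancy (first record on ties, which keeps 'A' in normally
ordered files). Ligand extraction takes all HETATM atoms of the first
(chain, residue-number) instance of the requested residue, refuses water,
and preserves file order — that order *is* the atom correspondence for
RMSD, so no reordering is ever applied. Structure screening accepts only
human, X-ray, resolution strictly < 3.0 Å, single-chain entries with a
co-crystal ligand of ≥ 100 Da (inclusive); unknown metadata fails closed
with an explicit `unknown-field` reason.

The docking box is the ligand's axis-aligned bounding box grown by
δ = 4.0 Å per face; a single-atom ligand degenerates to a (2δ)³ cube. RMSD
is the raw root-mean-square coordinate deviation in the shared docking
frame — no superposition and no symmetry correction, because redocking
happens in the receptor frame and the correspondence is positional. The
redock threshold is inclusive: RMSD ≤ 2.0 Å passes.

## Interaction typing

Contact criteria are distance-only on heavy atoms: hydrogen bond =
donor↔acceptor pair ≤ 3.5 Å, salt bridge = cation↔anion ≤ 5.5 Å,
hydrophobic = apolar-carbon pair ≤ 4.0 Å, π = aromatic-ring centroid to
centroid or to a cation ≤ 5.5 Å. Full interaction-profiler geometry
(donor–H–acceptor angles, ring-plane angles, π subtypes) is deliberately
omitted; this is a simplification and contact lists will be a superset of
an angle-filtered profiler's on real structures. Protein atom roles come
from a residue/atom-name template shipped as a TSV (backbone N donor except
proline, backbone O acceptor, Asp/Glu carboxylates as anions, Lys/Arg
side-chain nitrogens as cations, aliphatic side-chain carbons hydrophobic,
one aromatic ring per Phe/Tyr/His/Trp residue — the six-membered ring for
Trp). Ligand roles are inferred from connectivity (bonds = heavy-atom pairs
within 1.9 Å): nitrogens are donors/acceptors and amine-like nitrogens
cations; oxygens acceptors, terminal oxygens also donors unless part of a
carboxylate (then anions); carbons with no N/O neighbour hydrophobic;
5–6-membered C/N rings aromatic. Two deliberate deviations from common
profiler practice: hydrogens are never required (crystal structures rarely
have them), and aromatic carbons act only through the π channel rather
than doubling as hydrophobic contacts, which keeps ring–ring interactions
from spawning redundant hydrophobic records.

## Composite centrality

The thresholded network (combined score ≥ 400, inclusive; self-loops and
duplicate edges removed, duplicate pairs keep the maximum score) is treated
as undirected and unweighted — scores act only as the confidence filter.
Conventions, stated because no single convention is universal: normalized
betweenness; Wasserman–Faust component-scaled closeness; degree normalized
by N − 1; PageRank with damping 0.85 (tolerance 1e-12); eigenvector
centrality as the Perron vector of the adjacency matrix computed by dense
symmetric eigendecomposition, sign-fixed non-negative and unit-Euclidean
normalized. The eigendecomposition (rather than power iteration) is a
deliberate numerical choice: power iteration's residual scales with the
inverse spectral gap, which on small or near-bipartite graphs can exceed
any fixed tolerance, while the dense solve is exact to machine precision at
the network sizes involved (hundreds of nodes). Z-scores use the sample
(n − 1) standard deviation over all network genes; a column whose sd falls
below 1e-12·max(1, |mean|) is constant up to floating-point noise (e.g.
any centrality on a vertex-transitive graph) and maps to all-zero z rather
than amplifying that noise. Composite = 0.25·z_betw + 0.25·z_close +
0.20·z_deg + 0.15·z_eig + 0.15·z_pr, ranked descending with alphabetical
tie-break for reproducibility; the top 30 are flagged. Topology statistics:
density 2E/(N(N−1)), average shortest path length on the largest connected
component, global transitivity.

## Synthetic data

The generators define the test conditions; they are pure functions of
(spec, seed) using numpy's PCG64 stream, and each emits its ground truth.

**Compound libraries** sample a curated 69-SMILES panel spanning approved
oral drugs, clean fragment-like heterocycles, alert-bearing chemotypes
(catechols, quinones, rhodanines, nitroaromatics, Michael acceptors) and
deliberately non-drug-like matter (C30 alkanes, PEG chains, fatty
conjugates, peptides, glycosides). Panel strata are computed at run time
by the default scorer itself — no grades are hardcoded — and libraries are
drawn per-grade by largest-remainder apportionment of the requested mix
(default: 25/92/37/10/7 over 171, the distribution of a realistic
enrichment-derived screening list). Because strata are smaller than large
requests, sampling is with replacement; synthetic libraries therefore
contain repeated structures under fresh identifiers, and the deduplication
filter is exercised on purpose-built fixtures instead. What these libraries
do not emulate: the chemical diversity of a real enrichment hit list
(69 distinct structures versus hundreds) and any correlation between grade
and target activity, so passing tests show the scoring arithmetic and
reporting are correct, not that the panel predicts potency.

**Toy complexes** place each planted contact on its own icosahedral ray
from the origin: the ligand atom (or benzene-ring centroid) at 6 Å, its
protein partner at 6 Å plus a distance drawn inside the kind's cutoff
(0.1 Å inside at the top end; salt bridges start 0.5 Å above the H-bond
cutoff so they never double-type). With ≥ 63.4° between rays, every
cross-ray ligand–protein separation exceeds the widest cutoff + 0.5 Å, and
inert filler (glycine Cα) sits on a 14 Å shell, so the realized contact
set provably equals the planted one. At most 12 contacts fit the 12 rays.
These pockets have no fold, no sterics and no chemistry beyond the planted
roles — they validate the typing rules and cutoffs, not pose realism.

**PPI networks** use a Barabási–Albert backbone (attachment 3), edge
scores drawn uniformly from [150, 399] with probability 0.40 and from
[400, 999] otherwise (so ~60 % of backbone edges survive thresholding),
and an optional planted hub wired to 30 % of nodes with scores in
[700, 999]. The 311-node default mirrors a typical disease-module STRING
subnetwork's size. A hub touching 30 % of the network dominates every
centrality, so recovery failures indicate implementation faults, not
statistical bad luck.

## Configuration and reproducibility

All thresholds default to the documented constants (weights, grade bands,
score threshold 400, cutoffs 3.5/5.5/4.0/5.5 Å, δ = 4.0 Å, redock 2.0 Å)
and are validated (weights sum to 1, non-negative cutoffs, decreasing grade
bounds) before any stage runs; precedence is flags > config file >
defaults. Every command is deterministic given its inputs and seed; CSV
output is comma-separated UTF-8 with a header row.

## Known limitations

- Rule-based ADMET is a property-window screen, not a pharmacokinetic
  prediction; it shares inputs (MW, logP, TPSA…) with the other rule
  dimensions, so components are correlated.
- Contact typing without angle terms over-calls hydrogen bonds and π
  interactions on real structures.
- The ligand connectivity perception is geometric (1.9 Å) and will mistype
  unusual bond lengths or metal sites; metals, halogen bonds and
  water-mediated bridges are not modelled.
- Eigenvector centrality on a disconnected network concentrates on the
  component with the largest adjacency eigenvalue; rankings are intended
  for largely connected networks.
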