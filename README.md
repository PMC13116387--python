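# gradescreen

Computational support for structure-based virtual screening campaigns:
multi-criteria drug-likeness grading of compound libraries, docking-box
construction and redocking validation from co-crystal ligand geometry,
distance-cutoff protein–ligand interaction typing, and composite-centrality
hub-gene ranking in protein–protein interaction (PPI) networks. Every stage
ships with a synthetic-data generator carrying exact ground truth, so the
whole pipeline runs and is testable with no external downloads.

Intended users: computational chemists and bioinformaticians who triage
enrichment-derived compound lists before docking, and who need the
supporting geometry and network steps to be reproducible and unit-tested
rather than buried in one-off scripts.

## The scoring model

Each compound receives seven component scores, all normalized to [0, 1]:
Lipinski's rule of five, Veber's rule, and Ghose's rule (each scored as the
fraction of the rule's criteria passed), the quantitative estimate of
drug-likeness (QED, used raw), synthetic accessibility (Ertl–Schuffenhauer
SA score mapped by (10 − SA)/9 so higher = easier), a six-check rule-based
ADMET screen, and a PAINS/BRENK structural-alert penalty (0.5 per alert,
floored at 0). The total is a weighted linear combination

```
S_total = 0.15·S_Lipinski + 0.10·S_Veber + 0.10·S_Ghose + 0.20·S_QED
        + 0.15·S_SA + 0.20·S_ADMET + 0.10·S_alerts
```

mapped onto five left-closed grade bands: **A** ≥ 0.85, **B** [0.70, 0.85),
**C** [0.55, 0.70), **D** [0.40, 0.55), **F** < 0.40. A-grade compounds are
the candidates taken forward to docking.

The geometry stage derives the docking search volume from the
co-crystallized ligand's axis-aligned bounding box: center = (max + min)/2
and size = (max − min) + 2δ per axis with δ = 4.0 Å padding, and validates
poses by the raw coordinate RMSD in the shared docking frame with a 2.0 Å
redock threshold. Contacts are typed by heavy-atom distance cutoffs:
hydrogen bonds ≤ 3.5 Å, salt bridges ≤ 5.5 Å, hydrophobic ≤ 4.0 Å,
π interactions ≤ 5.5 Å (ring-centroid based).

Hub genes are ranked by standardizing five centralities (betweenness,
closeness, degree, eigenvector, PageRank) to Z-scores over a STRING-style
network thresholded at combined score ≥ 400, and combining them with
weights 0.25/0.25/0.20/0.15/0.15; the top 30 are flagged.

## Worked example

```sh
gradescreen simulate library --seed 4 --n 40 --out sim
gradescreen score --in sim/library.csv --out scorecards.csv
gradescreen summarize --in scorecards.csv
```

The numbered drivers under `analysis/` run the full pipeline on synthetic
inputs; `python analysis/02_score_library.py` prints, for the seeded
171-record library (48 unique structures after deduplication):

```
grade distribution over 48 unique compounds:
  A: n= 13   27.1%
  B: n= 18   37.5%
  C: n=  9   18.8%
  D: n=  4    8.3%
  F: n=  4    8.3%
mean S_total 0.728, median 0.791
-> 13 A-grade compounds advance to docking
```

i.e. counts per grade with half-up one-decimal percentages, the mean and
median total score, and the A-grade docking candidates.
`python analysis/05_rank_hub_genes.py` ranks the planted hub of the
synthetic 311-gene network first (composite 11.49 vs 4.46 for the runner-up)
and reports density 0.0142, average path length 3.314, clustering 0.0270
for the thresholded network.

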