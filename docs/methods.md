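# Methods

## Scope and model

phytonet implements the desk-side arithmetic of a network-pharmacology
study of a multi-compound preparation against a disease: formula annotation
of accurate-mass peaks, probability/score screens on target tables, set
algebra to a therapeutic target set, topological screens on the
compound-target and PPI graphs, hypergeometric over-representation
analysis, and assembly of the compound-target-pathway network. It does not
operate instruments or query web services: peak tables, prediction tables,
disease-target tables, PPI edge lists and annotation files are its inputs.

## Mass annotation

* Isotope masses (Da): C 12 (exact), H 1.00782503207, N 14.0030740048,
  O 15.99491461956, Na 22.9897692809, Cl 34.96885268, S 31.97207100,
  P 30.97376163 (CODATA/AME most-abundant isotopes).
* Adduct deltas (Da, singly charged, electron-corrected): [M+H]+
  +1.00727646, [M+Na]+ +22.98922142, [M−H]− −1.00727646, [M+Cl]−
  +34.96940126, [M+COOH]− +44.99820285.
* ppm error is signed, (observed − theoretical)/theoretical × 1e6, and
  reported rounded to one decimal place.
* Candidate enumeration is exact: depth-first over elements sorted by mass
  descending with branch-and-bound on the remaining achievable mass, then
  an RDBE ≥ 0 filter (valence model: C +1, N/P +½, H/Cl/Na −½, O/S 0 per
  atom, +1 constant). The nitrogen rule is deliberately *not* enforced —
  even-electron adduct ions make it unreliable. Default bounds
  C 0–50, H 0–100, N 0–10, O 0–20, S 0–3, P 0–3, Na 0–1, Cl 0–1 cover
  common phytochemistry with a tractable search space. Candidates are
  sorted by |ppm|, ties by fewer heteroatoms then Hill formula; widening
  the tolerance or the bounds can only add candidates.
* The bundled reference peak table carries a per-row `consistent` flag:
  rows whose reported 1-d.p. ppm error is reproduced exactly from the
  printed 4-d.p. m/z under these constants. 28 of 41 rows reproduce; the
  rest (e.g. SL4, SL15, SL23) were evidently computed from unrounded
  instrument values and are kept for context only, never asserted on.
  Per-row polarity is not printed explicitly and is assigned by the
  best-fitting adduct.
* A single accurate m/z at ±5 ppm does not identify a formula uniquely:
  `[M+COOH]−` of M is *exactly* isobaric with `[M−H]−` of M+CH₂O₂, and
  unrelated CHNO compositions can fall inside the window at higher mass.
  Rank-1 recovery rates on noisy synthetic peaks (roughly 25–40 % at
  ±4.5 ppm noise under generous CHNO bounds) quantify that ambiguity; real
  studies resolve it with MS/MS fragments and databases, which are out of
  scope here.

## Screens and set assembly

* Predictions: keep probability strictly > 0 (configurable threshold);
  per-compound sets and their union are deduplicated.
* Disease sources: screened independently at score ≥ the source's
  arithmetic mean, computed after collapsing duplicate genes to their
  maximum score (the collapse rule is this package's documented choice —
  score scales are not comparable across sources). A source with no score
  column is kept whole, matching curated databases that export no ranking.
  The maximum always survives, so every source keeps ≥ 1 gene.
* Gene symbols are treated as opaque canonicalized strings (uppercased,
  stripped); no alias or cross-database identifier mapping is attempted.
* The therapeutic target set is the intersection of the compound-target
  union with the union of screened disease sources.

## Networks

* All graphs are simple and undirected; nodes carry a role tag
  (compound / target / pathway); duplicate edges collapse, self-loops are
  rejected. Compound-target graphs are verified bipartite.
* Betweenness uses Brandes' algorithm over unweighted shortest paths
  (networkx) with endpoints excluded, normalized by 2/((n−1)(n−2)) where n
  is the whole-graph node count — also on disconnected graphs (the
  Cytoscape convention). Graphs with fewer than 3 nodes get betweenness 0.
* Main-ingredient screen: means of degree and betweenness are computed
  over compound nodes only; both inequalities are strict ("greater than
  the mean"), configurable to ≥.
* PPI: edges kept at combined score ≥ 0.9 (boundary inclusive) between
  therapeutic genes; genes left without an edge ("free genes") are not
  added. Raising the threshold is monotone (never adds nodes or edges).
* Hub ranking: degree descending, ties alphabetical; ties sharing the k-th
  degree beyond position k are reported in an explicit overflow list
  rather than silently dropped.
* Compound-target-pathway network: nodes are the selected pathways, the
  network targets belonging to at least one of them, and the compounds
  retaining at least one edge to such a target; edges are the restricted
  compound-target links plus target-pathway membership links.

## Enrichment

Upper-tail hypergeometric test per term; query genes outside the
background are excluded from the query size and counted in the run report;
terms with zero overlap are never reported. The screen is on raw p < 0.01
by default — no multiple-testing correction, mirroring common practice for
this workflow — with Benjamini–Hochberg available behind a flag. The
default background is the set of all annotated genes. Top-k selection (20
by default) is per category by enriched gene count, ties by smaller p then
term id.

## Synthetic study generator

The generator emits the five input tables plus a `truth` record, and is
fully deterministic given the seed; each table draws from its own RNG
sub-stream (SeedSequence spawn keys), so adding a table type never
perturbs existing draws.

Design choices worth knowing:

* **Counts are planted exactly, not in expectation.** The default
  configuration fixes the study scale: 41 compounds (32 connected through
  685 links to a 262-gene intersection; 7 planted main ingredients),
  1157 kept prediction rows over a 471-gene compound union, four disease
  sources screening to 2670/542/634/3 genes and merging to 3225, a PPI
  network with exactly 222 connected genes and 1205 super-threshold edges
  (10 planted hubs at degrees 37–56, non-hub degrees capped at 30, 40 free
  genes reachable only by sub-threshold edges), and 20 planted pathways
  covering exactly 132 network targets reached by exactly 29 compounds.
  Summary statistics of a generated study are therefore identical for
  every seed, while memberships, scores and orderings are seed-dependent.
* **Degree allocation.** Baseline connected compounds draw their degree
  from `targets_per_compound`; the planted ingredients split the remaining
  edge budget with ±20 % jitter, strictly above the overall mean. The
  presets are constructed so that the planted/baseline degree ratio is
  about the configured boost (5×); the exact edge total takes precedence
  over the ratio.
* **Disease scores** are drawn in two separated strata — screened genes in
  [10, 40], filler genes in [0.2, 1.0], four filler rows per screened gene
  — so the per-source mean provably falls strictly between the strata and
  the score ≥ mean screen keeps exactly the planted genes for any seed.
  The configured family (lognormal / uniform) only shapes the distribution
  inside its stratum; a "constant" source has no score column and is kept
  whole.
* **Annotation planting.** Planted terms add query genes until their
  hypergeometric p is ≤ 1e−3, then pad with non-query genes according to
  the planted overlap fraction. Planted KEGG terms draw their query-side
  members only from the designated pathway-target set (so the CTP counts
  are exact), and decoy KEGG terms are drawn disjoint from the query so
  the set of significant pathways is exactly the planted one; decoy GO
  terms sample the full background and so occasionally overlap the query,
  which exercises the screen realistically.
* **Peaks** draw formulas from the bundled reference pool; observed m/z is
  the theoretical adduct m/z perturbed uniformly within ±4.5 ppm, with a
  configurable fraction pushed to 7.5–15 ppm as planted negatives. The
  formate adduct is excluded from the generator pool because its exact
  isobar makes "recover the generating formula" ill-posed (see above).
* The ten reserved hub symbols (PIK3R1, PIK3CA, SRC, MAPK1, AKT1,
  HSP90AA1, HRAS, STAT3, FYN, RHOA) are used for fixture realism; all
  other genes are synthetic symbols.

What the generator does **not** emulate: realistic chemistry (no
structures, no fragment spectra), realistic PPI topology beyond planted
degrees (no clustering, no community structure), correlated annotation
terms (no GO DAG), or cross-source gene-identifier noise. Passing recovery
tests therefore demonstrates the correctness of the screens and rankings
under the planted-signal model, not robustness to real-data pathologies
such as identifier drift or annotation bias.

## Pipeline

Stages run in the order peaks (optional) → target assembly → networks →
enrichment → compound-target-pathway network, writing every intermediate
artifact (gene sets, centrality tables, GraphML/SIF graphs, enrichment and
bubble tables) plus a JSON run report. An empty therapeutic intersection
stops the run with an explicit "empty therapeutic set" status. No artifact
embeds a timestamp (the log format is timestamp-free), so re-running on
identical inputs is byte-identical; the report differs only through the
configured paths it embeds.

## Problem sizes used in tests and the acceptance script

The test suite exercises the full-scale study once and otherwise uses a
reduced preset (12 compounds, 30-gene intersection, 24-node PPI, 34
annotation terms) for repeated-seed checks: 100 seeds for planted-set
recovery in the suite, 50 in the acceptance script. Oracle-equivalence
checks run brute-force enumeration at the sizes where it is exact and
affordable: all-pairs path counting on 200 random graphs of ≤ 10 nodes,
full enumeration of all C(N, n) query draws for backgrounds N ≤ 15, and a
full-grid formula enumerator over C ≤ 20, H ≤ 40, N ≤ 5, O ≤ 10 for 100
random compositions.

## Known limitations

* Formula identification from a single m/z is reported with its intrinsic
  ambiguity (see mass annotation); no isotope-pattern or MS/MS scoring.
* Real database-derived counts (e.g. term counts from a specific
  annotation release, degrees from a specific PPI release) depend on the
  release state and cannot be regenerated from first principles; the
  package validates arithmetic consistency and planted-truth recovery
  instead.
* The betweenness normalization convention matters when comparing numbers
  across tools; phytonet documents and tests one convention rather than
  fitting any externally reported mean.
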