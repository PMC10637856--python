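# Methods

## Model and assumptions

`openmoa` infers the mechanism of action of a perturbation (a drug binding
a target, or a gene being modulated) from three ingredients: a typed
directed interaction network, a cell-context expression filter, and a
perturbation signature. Three modelling assumptions underpin everything:

1. the merged network is treated as the universe of candidate
   interactions — mechanisms outside it cannot be found;
2. edges are independent events, so joint probabilities factor into
   products;
3. signal propagates along topologically shortest paths (unweighted edge
   count).

Because expression changes are assumed to be TF-mediated, an admissible
path from the start node to a responding gene must end with a regulatory
edge leaving a transcription factor. Minimality is defined *within* the
admissible set: a shorter path that ends in a PPI edge neither counts nor
shortens the admissible length.

## Scoring

For endpoint *ep* with Benjamini–Hochberg FDR `f` (its penalty score) and
`m` admissible shortest paths, every distinct edge in the union of those
paths receives `f^(1/m)` once per action — an edge lying on several of the
`m` paths is not penalized repeatedly. Across actions, an edge's penalties
multiply; confidence is `1 − penalty`. Interpretation: the FDR is the
probability the endpoint did not respond; if it did respond, at least one
of the `m` routes was active, and the even split spreads that evidence
across the candidate routes.

### Numerical choices

* All products are accumulated as sums of `log10` terms. Signatures with
  thousands of endpoints push penalties far below the smallest positive
  double (`0.5^1000 ≈ 10^-301`); the log field of every weighted edge is
  therefore authoritative, and the linear `confidence` column can round to
  exactly 1.0 when the log is below about −16.
* Per-edge log contributions are sorted before summation (`math.fsum`), so
  the output is bitwise identical under any permutation of the endpoint
  list.
* Endpoint FDRs of exactly 0 (two-tailed p underflows at |z| ≳ 39) are
  floored at `1e-300` before taking logs.
* The constraint is implemented by restricting the endpoint's incoming
  edges to TF-regulatory ones inside a layered BFS that records the full
  shortest-path predecessor DAG; the test suite verifies this against the
  equivalent "search to each TF regulator, then append the final edge"
  formulation and against exhaustive DFS enumeration.
* Parallel edges of different types between the same ordered pair are
  distinct; a node path through such a pair expands into one edge sequence
  per type, and `m` counts edge sequences.
* `max_len` (default 8 edges) bounds the search; enumeration on dense
  graphs grows combinatorially and mechanisms longer than eight steps are
  not biologically interpretable here. Truncation returns "no path".
* Best-path ties (equal confidence products) resolve to the
  lexicographically smallest node sequence, then edge-type sequence, for
  reproducibility. The path aggregate is the product of edge confidences —
  consistent with the independence assumption; min-edge or mean-edge
  aggregation would be alternatives but are not implemented.
* The centric-subnetwork cutoff is the confidence at rank
  `ceil(fraction * n_scored)` of the descending sort over edges with
  confidence > 0; all boundary ties are included, so the output can exceed
  the nominal count.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_combined` | 700 | PPI combined-evidence threshold, strict `>` |
| `require_experimental` | on | PPI needs experimental or transferred evidence > 0 |
| `tpm_threshold` | 1.0 | context filter; a gene below this in *any* dataset is removed (strict `<`) |
| `max_fdr` | off | optional endpoint selection; by default every mapped signature gene is an endpoint, since high-FDR endpoints already contribute almost nothing |
| `max_len` | 8 | path-search bound, in edges |
| `fraction` | 0.01 | centric-subnetwork percentile |

Genes absent from an expression dataset are treated as TPM 0 (removed):
absence in a context profile is read as "not expressed", not "not
measured". Drug nodes are not genes and bypass the filter. Identifiers are
matched verbatim (no case folding), and one identifier acting both as a
drug and as a TF is an error rather than a silent merge. FDRs are always
computed on the *full* signature before mapping onto the network;
adjusting after subsetting would understate the original multiplicity.

## Synthetic data: what it emulates and what it does not

`synthdata` emits the exact table schemas of the real inputs (typed edge
lists with STRING-style integer score columns, gene/TPM tables, gene/Z
signatures) with one mechanism chain planted:
`drug → P1 → … → TF → gene`. Defaults — 3 drugs, 20 proteins, 5 TFs, 40
genes, PPI density 0.08, regulatory density 0.05, chain length 4, DE
fraction 0.05 at FDR scale 10⁻⁶ — give a network of a few dozen nodes in
which multiple equal-length routes occur regularly. Around 15% of
generated PPI rows carry failing evidence scores so ingestion filtering is
always exercised; five decoy signature genes never map to the network.

Planted differentially expressed genes sit in the planted TF's regulon;
the DE gene at rank *i* gets two-tailed `p = scale·i/n`, which the BH
step-up maps to an FDR of exactly `scale`. Two guard rules protect the
ground truth: background edges never join two planted-chain nodes (no
shortcuts around the chain), and no background TF regulates a planted DE
gene. With the default chain (`P1 → P2 → TF`, two hops) no strictly
shorter admissible route to the planted gene can arise, so the planted
edges always sit among the shortest paths; longer planted chains can be
shortcut through two background hops and carry no such guarantee.

The generator does **not** emulate scale-free topology, CMap
moderated-Z statistics, identifier-mapping noise, literature bias, or
correlated expression between datasets. Passing the planted-recovery tests
therefore demonstrates correctness of the machinery under the stated
assumptions, not performance on real perturbation data.

### Recovery protocol

`planted_path_recovery_rate` reruns the full pipeline on reseeded
replicates and counts those in which every planted edge downstream of the
start lies in the top-fraction (default 5%) centric subnetwork. Endpoints
are selected at an FDR cutoff of 100× the planted DE scale (capped at
0.05): planted genes pass with two orders of magnitude to spare while null
genes essentially never do. In the noise-free condition — exactly one
planted endpoint — the single action splits its penalty evenly, so all
planted edges tie at the top confidence and recovery is exact; with two or
more DE endpoints the shared upstream chain becomes *strictly* more
confident than each terminal regulatory edge, which is a genuine property
of the scoring (shared edges accumulate evidence), not an artefact.

## Known limitations

* Confidence measures probability of involvement, not effect size or
  contribution; suboptimal-confidence paths can still matter biologically.
* All-shortest-path enumeration can blow up on dense graphs; `max_len`
  truncates rather than samples.
* File round-trips of a network keep only nodes that carry at least one
  edge; isolated nodes (possible after aggressive context filtering)
  survive in memory but not in the edge-list export.
* Problem sizes in the test suite and acceptance script (networks of tens
  of nodes, 20 replicates) are chosen so the whole verification runs in
  minutes on one core; the algorithms themselves are deterministic at any
  size.
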