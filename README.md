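# openmoa

Mechanism-of-action (MoA) inference on typed multi-omics interaction
networks.

Network-based drug repurposing can nominate a compound for a new
indication, but it usually cannot say *how* the compound produces the
transcriptional changes that motivated the nomination. `openmoa` addresses
that gap for systems biologists and computational pharmacologists: given a
directed network that merges drug→target edges, protein–protein
interactions (PPIs), and transcription-factor (TF)→gene regulatory links,
together with a cell-context expression filter and a perturbation
signature, it scores every edge by how likely it lies on an active
signalling route from the perturbed node to the responding genes, and
extracts the most probable step-by-step mechanism.

## The model

Three assumptions drive the method: the merged network is treated as the
universe of possible interactions, edges are independent events, and
signal travels along shortest paths. Expression changes are taken to be
TF-mediated, so every admissible path must end with a regulatory edge
leaving a TF (the *TF-last-edge* constraint). PPI edges are traversable in
both directions; drug→target and TF→gene edges keep their curated
direction.

For a starting node *s* (the drug-binding target or modulated gene) and
one responding *endpoint* gene *ep*, the set of all minimum-length
admissible paths is a *drug action*. The endpoint's Benjamini–Hochberg FDR
— the probability-like weight that its expression did not really change —
is its penalty score, PScore(ep), computed from the signature Z-scores via
two-tailed normal p-values, p = 2·(1 − Φ(|z|)). If the endpoint responded,
at least one of the *m* shortest paths must be active, so each distinct
edge of the action receives the penalty evenly as an m-th root:

    PScore(se) = PScore(ep)^(1/m)

An edge shared by *n* actions (a *common edge*) multiplies the penalties
it collected,

    PScore(ce) = PScore(se₁) · PScore(se₂) · … · PScore(seₙ)

and each edge is finally reported as a confidence:

    Confidence = 1 − PScore

Products over thousands of actions underflow double precision, so all
accumulation is done in log₁₀ space; the log field in every output table
is authoritative. Two summaries are derived from the weighted network: the
*centric subnetwork* (all edges in the top fraction — default 1% — of
positive confidences, boundary ties included) and the *best MoA path*
between the start and a chosen endpoint (the constrained shortest path
maximizing the product of edge confidences).

Before scoring, the network is restricted to the cell context: a gene is
dropped if its expression is below a TPM threshold (default 1.0, strict)
in **any** of the supplied expression datasets. PPI evidence is filtered at
ingestion: combined score strictly above 700 and positive experimental or
experimental-transferred evidence.

## Worked example

Real interaction resources cannot ship with a package, so `openmoa`
includes a seeded generator that emits the same table schemas with a known
mechanism planted inside (see `openmoa.synthdata`). The snippet below
plants the chain `DRUG01 → P001 → P002 → TF01 → G001`, makes `G001` the
only differentially expressed gene (FDR ≈ 10⁻⁶), and runs the full
pipeline from the drug target `P001`:

```python
import tempfile
from openmoa import SynthesisSpec, generate_fixture, run_fixture_pipeline, best_moa_path
from openmoa.synthdata import default_recovery_max_fdr

spec = SynthesisSpec(seed=7, de_fraction=0.02)
with tempfile.TemporaryDirectory() as tmp:
    manifest = generate_fixture(spec, tmp)
    net, weighted, sub = run_fixture_pipeline(
        tmp, manifest, fraction=0.05, max_fdr=default_recovery_max_fdr(spec)
    )
    ...
```

which prints:

```
planted mechanism: DRUG01 -> P001 -> P002 -> TF01 -> G001
context network: 29 nodes, 48 edges
edges with confidence > 0: 3
   P001 -> P002  ppi        confidence=0.999999
   P002 -> TF01  ppi        confidence=0.999999
   TF01 -> G001  regulatory confidence=0.999999
best path: P001 -> P002 -> TF01 -> G001 (path confidence 0.999997)
```

With a single responding endpoint there is one action with m = 1, so every
edge on the unique admissible path carries the endpoint's penalty of 10⁻⁶
— confidence 0.999999 — while all background edges stay at 0. The path
query recovers exactly the planted mechanism; its aggregate confidence is
the product of the three edge confidences.

The same stages are available from the shell:

```sh
openmoa synth --spec spec.yaml --out fixture/
openmoa build --drug-targets fixture/drug_target.tsv --ppi fixture/ppi.tsv \
              --regulatory fixture/regulatory.tsv --out network.tsv
openmoa context --network network.tsv --expression fixture/expression_a.tsv \
                --expression fixture/expression_b.tsv --tpm 1.0 --out context.tsv
openmoa signature --in fixture/signature.tsv --out sig.tsv
openmoa score --network context.tsv --signature sig.tsv --start P001 --out weighted.tsv
openmoa subnet --weighted weighted.tsv --fraction 0.01 --out subnet.tsv
openmoa path --network context.tsv --weighted weighted.tsv \
             --start P001 --end G001 --out path.json
openmoa run --config config.yaml   # all of the above from one YAML
```

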