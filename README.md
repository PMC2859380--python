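# interoscore

Cross-species interolog prediction, interaction confidence scoring, and
interactome topology validation.

Most binary protein–protein interaction (PPI) data cover a small fraction of
any proteome, and coverage is wildly uneven across organisms. Because
orthologous proteins tend to keep their interaction partners, an interaction
observed in one species predicts a candidate interaction — an *interolog* —
between the orthologues in another. `interoscore` implements that transfer
for an arbitrary set of species (the default registry is human, mouse, fly,
worm, yeast), merges per-database PPI files into non-redundant interactomes,
attaches a confidence score to every known and predicted interaction, and
validates the combined networks with small-world topology diagnostics and
degree-preserving null models. Output is Cytoscape-compatible (SIF +
edge-attribute files). It is written for computational biologists who want
interolog transfer and its quality controls as a library and CLI over plain
TSV inputs, without coupling to any particular database snapshot.

## The score family

For a protein with contributing orthologues in a supporting species at
percent identities $I_1 \ge I_2 \ge \dots \ge I_n$:

* **OrthoScore** $= \sum_i r_i^2$ with $r_i = I_i / I_1$ (a one-to-one
  orthologue scores exactly 1; extra co-orthologues add less the weaker their
  homology).
* **SingleSpeciesScore** $=$ OrthoScore(A) $\times$ OrthoScore(B) for the two
  partners, per supporting species.
* **SpeciesScore** $= \sum_{s \in \text{supporting species}}$
  SingleSpeciesScore$_s$ ( $+\,1$ for the home species when the interaction is
  experimentally observed there). Species with orthologues but no observed
  interaction are never penalised.
* **ExperimentScore** $N$ = number of distinct (experiment type, evidence id)
  records across the interaction and all supporting interologues.
* **ExperimentQualityScore** $= \sum_e q_e$ over distinct experiment types,
  where $q_e$ is the fraction of interactions annotated by experiment type
  $e$ that also appear in a reference interaction set.
* **InteroScore** $=$ SpeciesScore $\times$ ExperimentScore $+$
  ExperimentQualityScore.

Each interaction also carries a **SpeciesNotation** string of genus initials:
uppercase where the interaction is observed, lowercase where both partners
have orthologues but no interaction is known (e.g. `HdC`: observed in human
and worm, predicted in fly).

## Worked example

A fly pair (FA, FB) is unknown in fly, but FA has three human co-orthologues
(92 / 87 / 72 % identity) all interacting with HB (one-to-one orthologue of
FB), and the one-to-one worm orthologues also interact:

```python
import interoscore as ic
from interoscore.ppi import EvidenceRecord, Interaction, Interactome

records = []
for g1, s1, g2, s2, htype, pid in [
    ("FA", "dmel", "HA1", "hsap", "one2many", 92.0),
    ("FA", "dmel", "HA2", "hsap", "one2many", 87.0),
    ("FA", "dmel", "HA3", "hsap", "one2many", 72.0),
    ("FB", "dmel", "HB",  "hsap", "one2one",  75.0),
    ("FA", "dmel", "CA",  "cele", "one2one",  60.0),
    ("FB", "dmel", "CB",  "cele", "one2one",  55.0),
]:
    records.append(ic.OrthologyRecord(g1, s1, g2, s2, htype, pid))
    records.append(ic.OrthologyRecord(g2, s2, g1, s1, htype, pid))
ortho = ic.OrthologyMap(records)

def interactome(code, pairs):
    tome = Interactome(code)
    for i, (a, b) in enumerate(pairs):
        tome.add(Interaction(pair=(a, b), species=code,
                 evidence={EvidenceRecord("MI:0018(two hybrid)", f"E-{code}-{i}")}))
    return tome

known = {
    "hsap": interactome("hsap", [("HA1", "HB"), ("HA2", "HB"), ("HA3", "HB")]),
    "cele": interactome("cele", [("CA", "CB")]),
    "dmel": interactome("dmel", []),
}

registry = ic.default_registry()
(prediction,) = ic.predict_interologues(known, ortho, "dmel", registry)
table = ic.QualityRatioTable(ratios={"MI:0018(two hybrid)": 0.283})
bundle = ic.score_prediction(prediction, table)
```

This prints:

```
predicted pair:         ('FA', 'FB')
species notation:       HdC
SingleSpeciesScores:    {'cele': 1.0, 'hsap': 2.501}
SpeciesScore:           3.501
ExperimentScore:        4
ExperimentQualityScore: 0.283
InteroScore:            14.289
```

The human OrthoScore of FA is $1.0^2 + 0.945^2 + 0.78^2 = 2.501$: the three
co-orthologues are scaled to the strongest one, so paralogous support counts,
but weaker homology counts less. Worm contributes 1.0 (one-to-one on both
sides), hence SpeciesScore 3.501. Four distinct experiments back the
supporting interologues (three human, one worm), and the single experiment
type carries quality ratio 0.283, giving InteroScore
$3.501 \times 4 + 0.283 = 14.289$. Predictions with InteroScore $\ge 1.5$
(`filter_high_confidence`, CLI `score --cutoff 1.5`) form the
high-confidence tier.

## CLI

```
interoscore simulate --outdir fixture --seed 1     # synthetic multi-species inputs
interoscore ingest   --species hsap --synonyms fixture/synonyms.tsv \
                     --ppi intact fixture/intact.tsv --ppi dip fixture/dip.tsv \
                     --ppi bind fixture/bind.tsv --out hsap.merged.tsv
interoscore predict  --orthology fixture/orthology.tsv \
                     --interactome hsap.merged.tsv --interactome dmel.merged.tsv \
                     --target dmel --out predictions.tsv
interoscore score    --orthology fixture/orthology.tsv --target dmel \
                     --interactome hsap.merged.tsv --interactome dmel.merged.tsv \
                     --reference-edges fixture/reference_edges.tsv --out scores.tsv
interoscore topology --interactome dmel.merged.tsv --seed 1
interoscore query    --genes genelist.txt --orthology fixture/orthology.tsv \
                     --interactome dmel.merged.tsv --target dmel
interoscore export   --orthology fixture/orthology.tsv --target dmel \
                     --interactome dmel.merged.tsv --outdir cyto/
```

`simulate` emits a complete, seeded fixture directory (orthology table,
per-database PPI TSVs, synonym table, reference edge set, gene list) together
with `groundtruth.json` recording everything that was planted, so the whole
pipeline is exercisable without any database download.

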