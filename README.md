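# nguild

Genome-resolved nitrogen-cycle guild inference for metagenome-assembled
genomes (MAGs).

Engineered nitrogen-removal communities — in particular partial
nitritation/anammox (PNA) granules, where aerobic ammonia oxidizers (AOB)
and anammox bacteria (AnAOB) convert NH3 to N2 with no added organic carbon
— carry a large heterotrophic fraction whose role is encoded in truncated
respiratory pathways and biosynthetic auxotrophies. `nguild` turns per-MAG
gene annotations into that functional picture:

* **QC and filtering** — annotation hits kept at E < 1e-5, bit score > 60,
  identity > 30%; MAGs kept at completeness ≥ 70% or zero contamination;
  deterministic dereplication of redundant bins.
* **Pathway calls** — declarative step/alternative-enzyme definitions with
  the dropout-tolerant completeness rule: a pathway of > 2 steps may miss
  one step; shorter pathways need every step. Autotrophy is called by
  carbon-fixation key genes (CBB, Wood–Ljungdahl, rTCA, 3-HP, 3-HP/4-HB).
* **Nitrogen census and guilds** — per-genome flags over amo, hao, hzs,
  hdh, nxr (clade-labelled), nar/nap, nirS/nirK, nirBD/nrfHA, norBC/norZ and
  nosZ clades; guild calls for AOB, AnAOB, canonical NOB, comammox,
  DNRA-complete (nar ∨ nap plus nrfHA ∨ nirBD) and complete denitrifiers
  (nar ∧ nir ∧ nor ∧ nosZ).
* **NOx exchange network** — marker flags license substrate→product edges
  over the nitrogen intermediates; an intermediate is an exchange candidate
  when some genome produces it but cannot consume it while another consumes
  it but cannot produce it (NO exchange between truncated denitrifiers and
  nirK-less anammox genomes is the motivating case).
* **Auxotrophy/complementarity** — 20 amino-acid and 8 B-vitamin
  prototrophy matrices, provider/dependent splits per compound.
* **Read screen** — semi-global recruitment of reads against marker
  references at ≥ 85% identity and ≥ 90% query coverage, reported as reads
  per million (RPM).

A packaged 55-MAG fixture reproduces a published PNA reactor community at
the level of every printed gene-content statement, with a constraint file
that is checked by two independent code paths. A seeded simulator generates
communities with known guild labels and completeness-driven gene dropout
for property testing.

## Worked example

```bash
nguild make-fixture --out-dir run/fixture
nguild report --annotations run/fixture/annotations.tsv \
              --quality run/fixture/quality.tsv --out-dir run/report
```

`run/report/report.txt` begins:

```
Nitrogen-cycle guild report
===========================
Genomes passing QC: 55

Marker census:
  nitrate reductase operon (nar): 23/55
  nxr/nar homolog carriers: 28/55
  nitrite reducers (nirS|nirK): 27 (nirS 8, nirK 19)
  nir and nar: 7
  NO reducers (norBC|norZ): 8 (norBC 5, norZ 3)
  nor and nir: 7; nor, nir and nar: 4
  nosZ clade I: 1; clade II: 20
  nrfHA: 12; nirBD: 2
  nitrate reducers with nxr-as-nar: 25

Guilds:
  AOB: 3 (AOB1, AOB2, AOB3)
  AnAOB: 3 (AMX1, AMX2, AMX3)
  NOB_canonical: 0 (none)
  comammox: 0 (none)
  DNRA_complete: 5 (ACD2, CFX11, CFX8, CLB2, CLB3)
  denitrifier_complete: 1 (PRO3)
Autotrophs: 9 (AMX1, AMX2, AMX3, AOB1, AOB2, AOB3, CFX7, PRO3, PRO5)
```

Reading: of 55 genomes, 23 can respire nitrate and 27 nitrite, but only
PRO3 carries a complete denitrification pathway — truncated NOx respirers
dominate. Nineteen genomes can make NO but not consume it, while the
anammox genomes AMX2 and AMX3 (lacking nirK) consume NO without producing
it, so NO appears as an exchange candidate in
`run/report/nox_exchange.json`. The accompanying `summary.json` holds every
number in machine-readable form; `aa_matrix.tsv` / `vitamin_matrix.tsv`
show, e.g., PRO4 as the only fully amino-acid-prototrophic genome and
cobalamin (B12) synthesis confined to AMX1/AMX2.

The same machinery is available as a library:

```python
from nguild import build_fixture, census_community, community_counts, qc_filter

community = qc_filter(build_fixture())
counts = community_counts(census_community(community))
print(counts["narGHIJ"], counts["nitrite_reducers"])  # 23 27
```

## Layout

```
src/nguild/
  core_model.py       # types, TSV/JSON I/O, hit filter, QC, dereplication
  pathway_engine.py   # pathway definitions, completeness rule, autotrophy
  nitrogen_census.py  # marker census, guilds, community summaries
  nox_network.py      # transformation edges, endpoints, exchange network
  auxotrophy.py       # prototrophy matrices and complementarity
  read_screen.py      # semi-global read recruitment and RPM
  synthetic_data.py   # packaged fixture, constraint validation, simulators
  cli.py              # `nguild` subcommands and the pipeline report
  data/               # markers.yaml, pathways.yaml, ncycle_rules.yaml,
                      # fixture.yaml (all editable, schema-documented)
docs/methods.md       # model, assumptions, parameter rationale, limits
```
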