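# Methods

`nguild` infers community-level nitrogen-cycle structure from the gene
content of metagenome-assembled genomes (MAGs). Its intended setting is an
engineered partial-nitritation/anammox (PNA) community — aerobic ammonia
oxidizers (AOB) and anammox bacteria (AnAOB) on a heterotrophic background —
but every rule is declarative and the pipeline applies to any annotated
genome collection.

## Input model and filtering

The unit record is a MAG with CheckM-style completeness and contamination,
an optional relative-abundance estimate, and a set of annotated genes.
Annotation hits are retained when E-value < 1e-5, bit score > 60 and percent
identity > 30, all strict; presence-only tables (no statistics) pass
unchanged. Best-hit selection is delegated to the upstream annotation step —
the filter is purely row-wise. MAG QC keeps genomes with completeness ≥ 70%
*or* exactly zero contamination; the second clause deliberately admits
small, clean bins. When redundant bins of one MAG exist, dereplication ranks
by completeness, then contamination, then assembly size; the precedence
among the three criteria is a package decision (completeness first, because
downstream pathway calls degrade with gene loss, not with modest
contamination).

Gene identifiers are case-normalized; KEGG orthology ids are mapped to
symbols through an alias table in the marker file. Labels that cannot be
read off a symbol — nosZ clade I vs II, and whether an nxr/nar homolog is of
the canonical-NOB clade, the anammox clade, or the periplasmic NOB/AnAOB
group — must arrive pre-resolved as distinct symbols (`nosZ_cladeII`,
`nxrA_anammox`, `nxrA_periplasmic`, `nxrA_canonical`); assigning them is a
phylogenetic task outside this package's scope.

## Pathway-completeness heuristic

A pathway is an ordered list of steps; each step lists alternative enzymes
and counts as present when any one is encoded. A pathway with more than two
steps is called present when at most one step is missing; pathways of one
step require it. The two-step case is not covered by that rule as stated;
we require both steps (the conservative reading, consistent with the
one-step case), with `allowed_missing` exposed for sensitivity analysis.
The one-missing-step allowance is what makes calls robust to draft-genome
dropout: at 95% per-gene retention ≥ 90% of truly present pathways are still
called present (measured by the dropout-robustness test).

The shipped amino-acid (20), B-vitamin (8: B1, B2, B3, B5, B6, B7, B9, B12)
and carbon-fixation (CBB, Wood–Ljungdahl, rTCA, 3-HP, 3-HP/4-HB) definitions
are a reconstruction modelled on KEGG module structure, defined from each
pathway's committed branch point so that diagnostic genes stay
pathway-specific. They are editable YAML; any vocabulary change belongs
there, not in code.

Autotrophy uses *key-gene screening*, not the one-missing-step rule: a
genome is an autotroph when all key genes of at least one fixation pathway
are present (e.g. rbcL + prkB for CBB, acsA + acsB for WL). Fixation marker
genes are diagnostic individually; tolerating a missing one would invent
autotrophs.

## Nitrogen census and guilds

The census reduces a gene set to boolean flags over marker groups. Operon
flags require the catalytic core only (narGH, norBC, amoCAB, hzsABC in
full), with accessory subunits (narIJ, amoDE) recorded but optional — the
weakest assumption consistent with flag-level reporting; requirements are
configurable per group. hao-like paralogs are counted (they are deduplicated
per copy, `haoA_like_01` …) but never affect guild calls; their hypothesized
reactions (NH2OH→NO, NO2−→NO) exist only as rule-table edges that are off by
default.

Guilds: AOB = amo ∧ hao; AnAOB = hzsABC ∧ hdh; comammox = amo ∧ any nxr;
canonical NOB = canonical-clade nxr ∧ autotrophy ∧ ¬amo ∧ ¬hzs;
DNRA-complete = (nar ∨ nap) ∧ (nrfHA ∨ nirBD); complete denitrifier =
(nar ∨ nap) ∧ (nirS ∨ nirK) ∧ (norBC ∨ norZ) ∧ nosZ (either clade). The
canonical-NOB definition is pinned to the canonical nxr clade on purpose: a
periplasmic NOB/AnAOB-group nxr in a carbon-fixing genome is *not* treated
as evidence of a nitrite oxidizer, because the direction of that enzyme is
unresolved.

The census summary counts carriers per group and per joint condition. The
`nxr_as_nar` switch adds genomes whose only nitrate-reduction candidate is a
periplasmic nxr-like gene to the nitrate-reducer count — the permissive
reading of an enzyme whose direction is unknown.

## NOx transformation network

Each true flag licenses substrate→product edges over
{NH3, NH2OH, NO2−, NO3−, NO, N2O, N2, NH4+, N2H4} via a declarative rule
table. Anammox nxrAB is emitted reversibly: its oxidative direction
(NO2−→NO3−) is the community's only nitrate source and is labelled as such
in the exchange report. Hydrazine synthase consumes NO and NH4+; hydrazine
dehydrogenase produces N2. Modelling N2H4 explicitly keeps anammox visible
as NO consumption — collapsing it would hide exactly the interaction of
interest.

Denitrification endpoint labels follow the linear chain
NO3−→NO2−→NO→N2O→N2 only (DNRA and anammox edges are reported separately):
the label is the maximal contiguous span a genome can run ("NO3->NO2",
"NO2->N2O", "full", "none"), with disjoint spans joined ("NO3->NO2+N2O->N2").

An intermediate is an exchange candidate when at least one genome produces
it without being able to consume it (donor) and another consumes it without
being able to produce it (acceptor). This is genomic potential; no kinetics,
stoichiometry or spatial structure is implied.

## Auxotrophy and complementarity

Per genome, presence vectors over the 20 amino-acid and 8 B-vitamin
pathways; per compound, the provider/dependent split (a partition of the
community) with compounds lacking any provider flagged community-wide
auxotrophies. The correlation of amino-acid prototrophy fraction with
completeness and abundance is reported as a Pearson r without any
significance gate — it is a descriptive check that prototrophy calls are not
a completeness artifact.

## Read screen

Reads are recruited against marker references by semi-global alignment:
query end-to-end, reference local, both strands, better strand kept.
Thresholds are 85% identity and 90% query coverage, both inclusive; reads
shorter than 45 nt (the common trimming floor) are never recruited.
Recruited counts are normalized to reads per million (RPM), with zero-hit
groups reported as 0 RPM.

Identity dialect: the aligner minimizes unit-cost edits (mismatches plus
internal gaps; reference overhangs free) and, among minimum-edit alignments,
maximizes matches; identity = matches / alignment columns. This
lexicographic objective makes the reported identity a well-defined function
of the sequence pair, independent of traceback tie-breaking — the property
the oracle tests rely on. Tools in this family differ in identity formulas;
this one approximates the "matches over columns" convention. Coverage is 1
by construction in this dialect; the threshold is still enforced to guard
alternative dialects.

## The packaged 55-MAG fixture

The study community ships as a declarative assignment (55 MAGs: 3 AOB,
3 AnAOB and 49 heterotrophs across 11 PRO, 15 CFX, 4 CLB and smaller
lineages) plus a constraint set restating every community-level observation
the assignment must satisfy: 23 nar carriers, 28 nxr/nar-homolog carriers,
27 nitrite reducers (8 nirS, 19 nirK), 7 nir∧nar, 8 NO reducers (5 norBC,
3 norZ) of which 7 carry nir and 4 all three, one clade-I nosZ (PRO3),
20 clade-II nosZ none with nor, 12 nrfHA, 2 nirBD, exactly
{ACD2, CFX8, CFX11, CLB2, CLB3} DNRA-complete, 25 nitrate reducers under
nxr-as-nar, 9 autotrophs, the AOB/AnAOB gene inventories, and the
amino-acid/vitamin statements (PRO4 the only full amino-acid prototroph,
PAT1 fully auxotrophic, B12 only in AMX1/AMX2, eight vitamin-devoid
genomes).

Two independent code paths enforce consistency: `build_fixture` evaluates
the constraints on the declared marker tokens before any gene set exists,
and `validate_fixture` re-derives every quantity through the census, guild
and pathway machinery from the emitted gene sets. Both passing is the
consistency proof; an injected contradiction aborts the build naming the
violated constraints.

Cells not pinned by a constraint are filled deterministically and are
non-authoritative: heterotrophs default to a single histidine auxotrophy
(so the unique-prototroph fact holds), vitamins default to
B1/B2/B3/B5/B6/B9 present with B7 and B12 absent (so no genome is fully
vitamin-prototrophic), and abundances are placeholders except the six
reported values. Two reconciliations worth recording: the printed name
lists leave the roster underdetermined, and the joint constraints force 11
(not 12) PRO genomes; and the clade-II nosZ sublists are treated as
membership constraints for narGHI carriers, with CLB1 and CFX2 carrying
narGH only — the reading under which all counts are simultaneously
satisfiable. Abundance-fraction statements are therefore not reproducible
from the fixture and are not asserted anywhere.

## Community and read simulators

`simulate_community` draws genomes from archetype gene sets (AOB, AnAOB,
complete denitrifier, DNRA, clade-II nosZ-only, plain heterotroph; default
mix 5/5/20/10/20/40%) plus random accessory genes, then thins each genome's
genes independently with retention probability completeness/100. The
dropout model is deliberately uniform — no operon linkage — so recovery
results are a lower bound on what linkage-aware dropout would give.
With dropout off, census + guild assignment recovers every label exactly;
at 90% completeness recovery stays ≥ 0.75 (documented floor; measured ≈
0.80 at n = 200), falling monotonically toward 70%. What these simulations
do **not** emulate: mis-binning, contamination-driven false positives,
annotation error, or correlated operon loss — so passing recovery tests
bounds dropout sensitivity only, not real-world annotation quality.

`simulate_reads` emits fixed-length windows of the references with
independent substitutions at a set rate, from random strands, with
provenance in the read id. At divergence 0 every read is recruited; at 0.20
recruitment collapses (expected identity 0.80 < 0.85).

## Numerical and determinism choices

Everything is a pure function of (inputs, config, seed): fixture
construction is seed-free and byte-stable, simulators use
`numpy.random.default_rng(seed)`, table and network exports are sorted, and
report bundles contain no timestamps, so identical runs are byte-identical.
Ties in dereplication fall back to input order; ties in read recruitment
prefer the earlier reference and the forward strand. Degenerate inputs:
empty annotation tables warn and yield empty communities; empty reference
sets and zero read totals are errors; unknown genes are ignored everywhere
(annotation vocabularies always exceed definition files), but unknown
compounds or marker groups in queries and rule tables are errors.

## Problem sizes

The default suite and the acceptance script run the full 55-MAG fixture
end-to-end, exhaustive pathway-rule enumeration to 10 steps, 200-genome
recovery simulations at four completeness levels, and a 100-pair alignment
oracle sweep at ≤ 200 nt — sizes chosen so the whole battery completes in
well under a minute on one CPU while still exercising every rule at the
scale the fixture defines.
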