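# Methods

## Analysis model

The pipeline assumes the standard clonal-expansion design: a clonal
parental cell population is exposed (or mock-exposed) to a compound,
single cells are isolated and expanded, and each colony's genome is
sequenced and variant-called jointly with the other colonies of its group.
Under this design a mutation private to one colony most plausibly arose in
that colony's founder cell during or shortly after exposure, whereas a
variant shared by two or more colonies predates exposure or is a
systematic calling artifact.

Two filters encode this:

* **Parental removal.** Variants in the supplied parental set are removed
  from every clone first. They are shared by construction and would fall
  to the exclusivity filter anyway; removing them first keeps the reported
  counts interpretable (the ledger separates "parental" from "shared").
* **Colony exclusivity.** A variant is kept for a clone only if no other
  colony of the same joint-calling group carries its identity key
  `(contig, pos, ref, alt)`. The census includes control colonies and
  colonies of other treatments in the group — the strictest reading, and
  the one that best suppresses shared artifacts. A
  `scope="treatment"` switch restricts the census to same-treatment
  colonies for sensitivity analyses. Genotype (het/hom) is deliberately
  not part of the key: the same key in two clones is non-exclusive
  regardless of zygosity.

## Classification

* **SBS96.** Strand collapse onto the pyrimidine: if the reference base is
  A or G, the trinucleotide window and the alternate base are
  reverse-complemented before naming. Windows that cross a contig end or
  contain `N` make the mutation *unclassifiable*; it is counted and
  logged, never guessed.
* **DBS78.** Doublets are derived by merging two same-clone SNVs at
  consecutive positions; native length-2 MNV records are accepted
  directly. Runs of ≥ 3 consecutive substituted positions are excluded
  from both the SBS and the DBS spectra and reported, so no event is
  counted twice and complex events are not misread as doublets. A merged
  doublet is never also counted as two SBS.
* **ID83.** 1 bp events are collapsed onto C/T and binned by homopolymer
  context. The homopolymer length of a 1 bp deletion *includes* the
  deleted base (a deletion out of a 4-long T run is `1:Del:T:3`; the 6+
  bin is `1:Del:T:5`); the repeat count of a 1 bp insertion counts only
  pre-existing adjacent copies (`1:Ins:T:0` means no neighbouring T).
  Deletions of ≥ 2 bp are repeat-type when at least one additional full
  copy of the deleted fragment flanks it (copy number capped at 5);
  otherwise microhomology-type when the fragment shares ≥ 1 bp of partial
  identity with either flank (the longer of the prefix match rightward
  and the suffix match leftward, capped at fragment length − 1 and at 5);
  otherwise `R:0`. Events longer than 50 bp and complex substitutions are
  unclassifiable. Indels are left-aligned before classification; the
  channel assignment itself counts context on both sides and is therefore
  insensitive to representation.
* Channel names and their order are frozen in plain-text tables shipped
  with the package (96/78/83 entries) and are bit-exact COSMIC-style
  names; every matrix and catalog uses this order.

## Spectra and burdens

Control subtraction is channel-wise against the **mean** of the group's
control clones, applied to each treatment clone *before* replicate
averaging, with negative differences clamped to zero. Clamped channel
counts are reported: heavy clamping flags a treatment whose burden barely
exceeds background. The alternative order (average treatment clones, then
subtract once) is available via `order="aggregate"`; with clamping the two
orders are not equivalent, and the default is the per-clone order.

Burden tables subtract **totals**, not channels: a clone's burden is its
total classified count minus the control-mean total, and can fluctuate
below zero for inert compounds. Channel-wise clamped subtraction would
inflate low-burden treatments by the sum of positive noise excursions
(~100 counts at a 750-count background), so it is reserved for spectra,
where non-negativity is required.

A compound's signature is
`to_probability(mean over clones of subtract_control(clone, control mean))`,
exposed as `compound_signature`. Cosine similarity is scale-invariant, so
counts and probabilities score identically; an all-zero spectrum is a
flagged state that refuses comparison rather than silently scoring 0.

## The simulator

`simulate_experiment` generates the complete input bundle with ground
truth. Its defaults mirror the emulated study design: three joint-calling
groups, five clones per condition, one group pairing a 700- and a
5500-burden compound with its control, one holding a 200-burden compound
plus three inert (zero-burden) compounds, and one holding the 25 000-burden
compound (with 0.6 doublet and 800 indel events per clone) plus control.
Each group has its own control clones, so the default design has 50
colonies. Per-clone mutation counts are Poisson with the stated means
(a negative-binomial switch with a variance/mean parameter is available,
default off); the endogenous background is 750 SBS and 100 indels per
clone. The background channel distribution is declared in the config:
`flat` by default, with a packaged `oxidative_like` alternative (C>A
enriched) reflecting the usual attribution of culture-acquired mutations
to oxidative damage under atmospheric oxygen.

The packaged compound signatures (`bap_like`, `norharmane_like`,
`mnng_like`, `nnk_acetate_like` and the DBS/ID fixtures) are synthetic
illustrations shaped qualitatively like the compound classes they are
named after — a C>A/C>T bulky-adduct profile, a similar but not identical
second bulky-adduct profile, a purine-5′ T>C alkylation profile, and an
even mix of C>T/T>A/T>C/T>G with 5′-A preference. They are not measured
spectra and carry no numeric provenance.

Placement is the inverse of classification: a channel is realized at a
uniformly chosen compatible site (trinucleotide sites via a precomputed
index, homopolymer runs via run-length encoding, repeat/microhomology
contexts via random probing) and verified by reclassification before being
accepted. When a small genome lacks an exotic context — say a 25 bp
tandem array for a `5:Del:R:5` deletion — a constructed context is
embedded into the reference first; embeds avoid every position another
placement relies on, are logged and counted, and the FASTA is written only
after all placements. Within a clone no two mutations may overlap or sit
on adjacent positions (which would create spurious doublets) unless an
adjacent pair is explicitly requested by a DBS channel; doublet burdens
are realized as true adjacent SNV pairs so the merging step is exercised.

What the simulator does **not** model: sequencing and alignment error,
caller false negatives/positives, subclonality and VAF structure,
selection during expansion, chromosome-scale genome organisation, and any
generative model of the real endogenous process beyond a stated channel
distribution. Passing recovery tests therefore demonstrates correctness
of the analysis logic under the stated generative model, not performance
on real sequencing data.

## Numerical and design choices

* Coordinates are 1-based inclusive (VCF `POS`) everywhere.
* Catalog columns must sum to 1 within 1e-3 on read and are renormalized
  to machine precision; probability spectra must sum to 1 within 1e-9.
* Catalog matching sorts by descending similarity with ties broken by
  catalog order, so rankings are deterministic.
* FILTER policy: only `PASS` or `.` records are accepted; everything else
  is dropped with a logged reason. Genotype and quality fields are
  ignored — presence of a passing record means the clone carries the
  mutation.
* Every reported count is traceable: per clone,
  `input = parental_removed + non_exclusive + isolated_SBS +
  merged_doublet_members + native_doublets + excluded_run_members +
  indels + unclassifiable`, checked exactly on every run.
* Groups without control clones abort the run: the analysis is defined by
  control subtraction, and silently skipping it would change the meaning
  of every downstream number.

## Validation scale and calibration

The end-to-end recovery test simulates the full design on a 5 Mb genome —
large enough that per-channel site availability never constrains placement,
small enough to run in seconds. A calibration run of the full pipeline
(seed 1) recovered the generating spectra with cosine 0.9997 / 0.9994 at
the 25 000- and 5 500-burden conditions, 0.994 at 700, and 0.917 at 200;
the frozen regression thresholds are ≥ 0.95 for burdens ≥ 5000, ≥ 0.8 at
700, and ≥ 0.85 at 200 (the last demonstrating degraded-but-usable
recovery at a burden well below the background of 750).

Recovered total burdens sit 2–3 % below the generative means (e.g.
~24 300 vs 25 000) because two clones of a group occasionally draw the
same identity key, and exclusivity then removes the variant from both —
an inherent property of the joint-group design that also affects real
experiments with recurrent sites.

## Known limitations

* DBS burdens of well under one event per clone (as for the packaged
  strong-mutagen fixture) yield spectra of 0–2 events; their derived
  "signatures" are anecdotal and are reported but not matched thresholds
  robustly.
* Transcriptional-strand-resolved (192-channel) classification, SV and
  copy-number classes, and de novo signature extraction (NMF) are out of
  scope; the package compares whole signatures only and performs no
  attribution/refitting.
* The VCF reader trusts upstream left-alignment of indel *keys* for the
  exclusivity census; classification is representation-insensitive, but
  the same indel called with different alignments in two clones would
  evade the exclusivity filter.
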