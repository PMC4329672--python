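# Methods

## Individual-information models

A binding-site model stores, for each window position *l* and base *b*, the
weight w(b, l) = 2 + log2 f(b, l) in bits, where f(b, l) is the base
frequency among aligned functional sites.  The individual information of a
candidate site, R_i, is the sum of the weights of its bases; under the
independence assumption between positions it is proportional to the binding
free-energy contribution of the site, with 0 bits the break-even point below
which spontaneous binding is not expected.  The training-set mean,
R_sequence, equals the sum over positions of 2 − H(l) (H = Shannon entropy)
— an identity the test suite enforces to 1e-9 bits with pseudocount 0 and no
correction.

Model geometry: window offsets are counted from the intron-side base at the
splice junction — the first intronic base of a donor (default window
[−3, +6]) or the last intronic base of an acceptor ([−25, +2]).  Offset 0 is
a real position.  The exon between an acceptor at *a* and a donor at *d*
spans [a+1, d−1] inclusive, which defines the exon length used by the gap
surprisal.

Numerical choices:

* **Pseudocount** — the weight formula is
  w = 2 + log2[(count + p) / (n + 4p)] with p = 0.5 recommended for
  user-built models and p = 0 for exact-identity work.  With p = 0 an
  unobserved base receives a finite sentinel weight (−20 bits,
  configurable) rather than −∞, so R_i stays finite while a forbidden base
  remains catastrophic.
* **Small-sample correction** — estimating entropy from n sites biases
  information upward by ≈ 3/(2 n ln 2) bits per position.  An optional flat
  correction with exactly that form can be subtracted from R_sequence; it
  is OFF by default and never touches individual weights, since the
  original tooling's exact correction is not specified in the sources
  available to us.
* **Ambiguity** — training records containing N are dropped with a warning
  (treating N as missing would bias frequencies); N in a *scanned* sequence
  contributes 0 bits at its position and flags the site, keeping R_i
  conservative.
* Models round-trip through a TSV + JSON sidecar format bit-exactly at 12
  significant digits.

## Variant interpretation

A variant's effect on a site is ΔR_i = R_i,final − R_i,initial.  Reported
alongside it are the **minimum fold change in binding affinity 2^|ΔR_i|**
(the exponential affinity relation) and the **residual strength**
100 × R_i,final / R_i,initial (undefined when the initial strength is not
positive).  These answer different questions — a 2.6-bit loss is ≥ 6-fold
weaker *affinity* yet may read as "67.5% residual" on the bit scale — and
both are printed side by side precisely because the bit ratio is easy to
misread as an affinity ratio.

Severity bins for natural sites (boundaries assigned to the less severe
class, since "more than 7 bits" is strict): ΔR_i < −7 deleterious, −7 to −4
probably deleterious, −4 to −1 leaky, ≥ −1 benign.  1.0 bit is the
significance threshold throughout: smaller changes are below reliable
experimental detection.

`analyze_variant` scores every model placement whose zero point falls
within the analysis window (default 54 nt circumscribing the variant; never
silently truncated below the largest model window) on the reference and
mutated sequences, re-anchoring through a monotone coordinate map for
indels — placements spanning a deletion are rescored across the junction,
not masked.  Annotated natural sites are always included even when outside
the window, so an engineered cryptic site can be compared with its cognate
natural site.  Categories: a natural site with R_i,final < R_i,min is
*abolished*; significantly weakened but still functional is *leaky*;
non-natural placements are *created* when they cross R_i,min upward, else
strengthened/weakened by ΔR_i sign.  R_i,min defaults to 1.6 bits
(genome-wide-style models) with 2.4 bits selectable for legacy curated
models.

Strand handling: the minus strand is scored on the reverse complement at
mirrored coordinates; reports always print the strand, and by default only
the annotated gene strand is analyzed (an antisense-strand site is a
classic misreading of tabular output), with both strands available by
option.

## Exon definition and branch points

Candidate exons are acceptor/donor pairs scored by
R_i,total = R_i,acceptor + R_i,donor − GS(length), with the gap surprisal
GS = −log2 of the binned empirical exon-length probability
(self-information).  Bins are user-configurable; the default is 16
log-spaced bins over [1, 10000] nt with a 2^−20 floor probability for empty
bins.  The bundled default length distribution is a **synthetic** log-normal
(median 120 nt, σ = 0.6 log-units) standing in for a genome-wide
constitutive-exon table, which users should substitute for production work.
A single regulatory factor per exon can contribute R_i minus a second
surprisal over its distance to the nearest natural site (default: an
exponential with 10-nt scale — elements concentrate within ~10 nt and the
penalty grows monotonically with distance).  When several sites of the one
factor are in play (e.g. pre/post variant), the strongest is used.

Isoform ranking orders candidates by descending R_i,total (ties: shorter
exon, then lower coordinate).  When a variant weakens a natural site by at
least `skip_threshold_bits` (default 7.0, i.e. ≥ 128-fold), the
exon-skipping isoform is inserted at the top of the post-variant ranking;
smaller drops can sometimes partially induce skipping, so the threshold is
exposed rather than hard-coded.

Branch-point scanning searches up to `search_nt` (default 100, hard maximum
400) upstream of an annotated acceptor for placements with R_i ≥ 0, records
the branch-adenosine-to-acceptor distance, and flags hits whose window
overlaps an annotated donor window (`context_ok = False`) — donor sequence
is a notorious source of spurious branch-point matches.

## Cryptic-site typing and pipeline flagging

`classify_event` partitions every (natural, cryptic) delta pair of the same
polarity: Type 2 when the natural site is significantly weakened AND the
cryptic strengthened/created; Type 1 when the cryptic is
strengthened/created and the natural unchanged (sub-significance drift of
the natural site is tolerated — the 1-bit threshold decides); Type 3 when
the natural is weakened and a pre-existing functional cryptic site is
unchanged; otherwise none.  A Type 2 label additionally requires the
variant's footprint to intersect both site windows — "simultaneous" means a
shared footprint; a distant independently-changing site falls back to the
natural-site rule.

`predict_activation` calls a typed event *likely* when the cryptic site is
functional and comparable to or exceeding the post-variant natural site
("comparable" = within `slack_bits`, default 1.0, the experimental
detectability threshold), downgraded beyond a 400-nt distance cutoff
(configurable; distant sites are less likely to be recognized even when
strong, and the reason is reported as text rather than silently dropping
the site).

The genome-pipeline filter retains deltas with (R_i,initial ≥ 0 or
R_i,final ≥ 0) and |ΔR_i| ≥ 1.0 bits, then prioritizes weakened natural
sites, activatable cryptic sites, and (lowest priority) strengthened
natural sites, dropping everything else with machine-readable reason codes.
The operation is pure, idempotent, and order-independent.

`interpret_variant` reduces a variant's delta list to one call
(abolished / leaky / neutral / type1-3).  A design point worth making
explicit: random sequence is replete with weak decoy sites (a few bits), so
an event is reported as the call **only when its cryptic site is
competitive with the natural site's full pre-variant strength** (within
`competition_slack_bits`, default 1.0).  Without this gate every abolished
natural site would be relabelled "type3" by whatever 2-bit decoy survives
nearby, which contradicts the observed pattern that activated cryptic
sites are generally comparable to or stronger than their cognate natural
sites.  The spec-level `classify_event` partition itself is unchanged.

## Concordance meta-analysis

`assess_concordance` scores predicted-vs-validated records by explicit
criteria: (a) predicted abolished and complete loss observed, with an
exception for assays that cannot separate the two alleles (heterozygote
RT-PCR); (b) predicted leaky with residual normal splicing observed, with
an exception when a much stronger cryptic site was activated; (c) a
strengthened natural site with normal or increased wild-type expression;
(d) a predicted cryptic site observed in use — *partially concordant* when
it was not ranked the predominant isoform, still counted toward the overall
percent; (e) regulatory-site predictions validated by binding experiments.
Records missing required fields are flagged uninformative and excluded from
the denominator.

## The synthetic-data generator

The generator emulates the study conditions without downloads.  Its
frequency matrices are stylized human splice-site compositions: a donor
with near-invariant GT and ~8.2 bits of total information (the average
strength of human donor sites is about 8 bits), an acceptor with a
polypyrimidine tract plus invariant AG at ~9.7 bits, and a 7-position
yUnAy-like branch-point motif (~2.9 bits) with a conserved branch
adenosine.  What it does **not** emulate: inter-position correlations, the
long low-information tails of real genome-wide models, GC heterogeneity,
and regulatory-element context — so passing tests demonstrate the
*arithmetic and logic* of the framework, not genome-scale calibration.

Toy genes (default three exons of 120 nt, introns of 300 nt) plant
designed sites of target strength (donors 8.0 bits, acceptors 9.5, ± 0.5)
on uniform random background (GC bias settable — higher GC raises decoy
density).  Site design is greedy weight arithmetic from the consensus with
two realism constraints: the GT/AG cores are pinned, and no G is introduced
in the acceptor tract (an AG-exclusion zone, as in real 3' splice sites) —
otherwise shifted placements acquire their own AG and outscore the planted
site.  The background is resampled (bounded, then an error) if any
accidental same-polarity placement within 100 nt reaches the planted site's
strength, keeping panel ground truth unambiguous.

Variant panels engineer one substitution per effect by weight arithmetic:
abolition (ΔR_i ≤ −8 at a donor), leaky weakening (−3.8 to −1.3 bits at an
acceptor, final ≥ R_i,min), a neutral mid-exon change, and the three
cryptic types via latent scaffolds planted with the gene — a knocked-out
strong donor deep in an intron whose restoring substitution creates it
(Type 1), an overlapping decoy 5 nt into the intron whose GT is completed
by the same substitution that weakens the natural +5 position (Type 2), and
a full-strength pre-existing decoy 20 nt downstream of a donor, inside the
default analysis window (Type 3; validated activated-cryptic distances
cluster within tens of nt of the natural site).  Candidate substitutions
whose side effects would move any competitive placement significantly are
rejected, so the planted label is the unique correct interpretation.  All
generators are deterministic functions of the seed.

## Problem sizes and limitations

The test suite runs at desk scale by choice: parameter recovery uses
100/1,000/10,000 sampled sites, the scan oracle 50 random 2-kb sequences,
the strength-differential simulation 104 events, and the end-to-end panel
one 1.6-kb gene with six variants; the whole suite completes in a few
seconds on one CPU.  Known limitations: only plus-strand exon tables for
c./IVS resolution (full HGVS is out of scope); a single regulatory factor
per exon; no multi-factor combinatorial scoring; no prediction of
deep-intronic mutation-created exons; the bundled exon-length distribution
is synthetic; and concordance scoring operates on structured record tables
— it does not parse free-text validation reports.
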