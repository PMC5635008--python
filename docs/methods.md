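# Methods

## Scope and model

`satellitome` re-implements, as a tested library, the desk-scale version
of a satellite DNA (satDNA) discovery-and-comparison analysis built
around a B-chromosome system: two individuals of one species are
sequenced (2 × 101 bp paired ends), one lacking (0B) and one carrying
(1B) a supernumerary B chromosome. Satellite families are mined from the
reads, catalogued into variants/families/superfamilies, quantified in
both genomes, screened for B-chromosome association, and compared
cytogenetically across species and B chromosomes.

Real libraries at the published scale (tens of Gbp) are out of reach on
a desk machine, so the package pairs every analysis stage with a
ground-truthed simulator and treats parameter recovery on synthetic
genomes as the primary evidence that the pipeline works. The published
per-family tables (catalogue, A-chromosome FISH patterns, B-chromosome
locations) ship as plain TSVs and drive the statistical stages directly.

## The simulator (`simgen`)

A genome is a haploid string: background i.i.d. over {A,C,G,T} (or at a
configurable A+T bias) with tandem arrays carved into it at random
non-overlapping positions, so the genome length equals the configured
background length exactly and every truth fraction is simple arithmetic
(copies × RUL / length). The 1B genome is the 0B string plus a B segment
of length round(f × |0B|), default f = 0.08.

* **Monomers** are uniform random sequences of the requested length and
  expected A+T fraction. A family may comprise several sequence
  variants; variant consensuses are derived from the ancestor at ~8%
  substitution divergence (pairwise identity ≈ 85–92%: distinct variants
  of one family under the 95/80 thresholds). Copies are split over
  variants with strictly decreasing weights (2^-k, normalised), so "most
  abundant variant" is well defined.
* **Intra-family divergence** is an evolutionary distance: each site of
  each planted copy receives a Poisson(d) number of substitution events,
  uniform over the three alternative bases. Realised mismatch to the
  consensus is therefore (3/4)(1 − e^(−4d/3)), and a Kimura-type
  estimator recovers d asymptotically. Substitutions only — no indels —
  so divergence estimates stay interpretable as K2P distances.
* **Superfamily partners** are derived from a named earlier family at a
  target identity in [0.5, 0.8) by forced substitutions at 1 − target of
  the sites.
* **B-restricted families** place tandem arrays only in the B segment;
  an optional count of dispersed single copies in the A complement
  emulates the low-but-nonzero 0B abundance that truly B-specific
  satellites show in practice (single scattered monomers, no tandem
  structure).
* **Reads**: fixed-length fragments with uniform starts, both strands,
  per-base substitution errors at a configurable rate (default 0.002 in
  the bundled scenarios), fixed placeholder qualities (Q37). Everything
  is deterministic given one master seed (child generators are spawned
  from it).
* **Ploidy convention.** Adding one B to a *diploid* A complement
  dilutes an A-only satellite by (f/2)/(1+f/2), not f/(1+f). The default
  read-simulation mode is therefore *diploid-equivalent*: the A portion
  (not the B) is duplicated before fragments are drawn, so the 1B
  template is A+A+B and the dilution factor is exactly 1/(1+f/2). The
  haploid convention remains available and the truth table reports both
  expectations.

What the simulator does **not** model: indels, quality-score profiles,
GC/coverage biases, PCR duplicates, transposon-interrupted arrays,
higher-order repeat structure, and between-individual copy-number
variation (the biological effect the published analysis invokes to
explain log2 anomalies beyond the dilution bound). Passing tests
therefore demonstrate algorithmic correctness under a clean substitution
model, not robustness to every artefact of real libraries.

## Discovery (`discovery`)

The mining loop follows the iterative protocol of graph-clustering-based
repeat discovery: sample 2×N read pairs, cluster, detect tandem
structure, build a consensus monomer, subtract homologous read pairs
from the library, double N, repeat. Key choices:

* **Clustering** is canonical k-mer sharing (k = 17) with an edge when
  two reads share ≥ 5 k-mers, taking connected components of ≥ 10 reads.
  K-mers carried by more than 50 sampled reads are treated as repeat
  words and union their bucket directly. This is deliberately simpler
  than community-detection layouts; the subsequent explicit tandem test
  replaces cluster-shape heuristics.
* **Low coverage is the working regime.** A satellite's effective
  coverage is its copy number times the genomic coverage, so repeat
  clusters form while unique background stays thin. Once a sample's
  background coverage approaches ~1×, background reads chain into large
  components and array-boundary reads bridge satellites into them. Two
  mechanisms keep detection working there: a *core-read filter* (keep
  reads whose k-mers recur in the cluster; boundary and background reads
  carry rare k-mers and drop out, with an adaptive cut so divergent
  families are not emptied) and per-read period voting that simply
  ignores non-periodic members.
* **Period detection.** For periods up to (L−1)/2 (two full copies per
  read) each read votes for its smallest self-comparison offset with
  identity ≥ 0.8 (within 0.03 of its best — guards against multiples);
  the modal period wins with ≥ 5 voters. Longer periods (up to 400 bp by
  default) go through greedy overlap assembly of core reads — reads from
  different copies overlap in monomer coordinate space, so the contig
  follows the periodic consensus — followed by self-alignment offset
  scoring on the contig; both paths agree where both apply (tested). A
  cheap precheck (some k-mer must occur in ≥ 20% of the cluster's reads)
  skips assembly for background chains. Up to three seed restarts guard
  against a poor seed read.
* **Consensus** is per-column majority over phase-aligned reads (or the
  period-folded contig), ties broken alphabetically, reported in
  canonical rotation (lexicographic minimum over rotations and strands).
* **Subtraction** removes a pair when either mate matches any mined
  monomer (tiled circularly, both strands) at ≥ 80% identity over ≥ 50%
  of the read — thresholds chosen to align with the 80% family-identity
  level; the published description does not state its filtering
  thresholds.
* **Stop rule**: mining ends after two consecutive iterations that add
  no monomer failing to group (≥ 80% rotational identity) with the
  catalogue so far, or when the library is exhausted. The one-iteration
  patience variant is a config switch; two bridges abundance gaps
  between family tiers at desk scale.

## Catalogue (`catalog`)

Rotational identity between monomers is the maximum over all rotations
of one sequence, on both strands, of global-alignment identity
(matches / alignment columns; gap columns count as mismatches), computed
with edlib and re-scored on the few best rotations. Grouping is
single-linkage at ≥ 95% (same variant), ≥ 80% (same family), ≥ 50%
(same superfamily), identities rounded to 0.1% first; a value exactly at
a threshold joins (switchable).

Because the metric maximises over ~2·RUL rotations and gapped
alignments, *unrelated* short monomers score ~50–60% — at or above the
superfamily threshold. A plain 50% cut would therefore merge most
same-length families, which contradicts the single superfamily observed
among 45 real families. Superfamily edges consequently must also exceed
a per-pair chance ceiling: mean + 3 sd of the identity against 20
shuffles of one sequence (deterministically seeded from the pair). The
80% and 95% levels are safely above chance and use the plain threshold.

Families are named `<Prefix>Sat<NN>-<RUL>` by decreasing 0B abundance
(ties: larger RUL first, then lexicographic consensus), NN zero-padded
to two digits; a consensus whose canonical rotation is TTAGGG (or a
perfect multimer) gets the `-tel` suffix. The family consensus is its
most abundant variant.

## Quantification (`quantify`)

Reads are masked against every variant consensus, tiled so alignment
sees the monomer as circular, on both strands. A read (or, failing
that, either read half) is assigned to the best variant when identity
≥ 0.70 over ≥ 30 bp — permissive enough for the most divergent families
seen in real satellitomes (~26%). Abundance is assigned nucleotides as
a percentage of all sampled nucleotides: the "total sampled" denominator
reproduces published table semantics where per-family percentages sum
to ~8%, unlike a mapped-reads denominator which would force 100%.

Substitution counts for divergence are taken at the best *ungapped*
placement of the segment on the tiled consensus (exact under the
substitution-only model; gapped optima absorb substitution clusters into
indels and bias divergence down), with a maximal-scoring-span trim
(match +1, mismatch −1.2) that removes near-random read ends — the
background tails of array-boundary reads — while leaving genuinely
divergent family sequence intact. Per-family divergence is the Kimura
two-parameter distance pooled over all assigned segments (transitions
and transversions summed before the K2P transform), not averaged per
variant. An exact-word prefilter (k = 13, either strand) skips reads
that cannot match; reads beyond ~20% divergence can occasionally be
missed by it, and it can be disabled for exact masking.

## B-chromosome comparison (`bchrom`)

Per family: log2(A1B/A0B) where both abundances are positive; families
with a zero are classified `undefined` and handled by the structural
path instead. Classification: positive log2 → B-enrichment candidate;
otherwise the relative decrease 1 − a1/a0 is compared against
(f/2)/(1+f/2) — the bound is phrased as an abundance decrease, so the
comparison happens on that scale rather than in log2 units. B-specific
candidates are verified structurally: `multimer_scan` counts 0B reads
containing ≥ 2 consecutive monomer copies (any phase, either strand,
each copy within 80% identity), and `targeted_recluster` selects up to
2 × 2500 monomer-homologous pairs per library separately and re-runs
clustering + tandem detection on each selection. The expected signature
of a truly B-restricted family is a positive log2 (or undefined a0) with
tandem structure in the 1B selection only.

## Cytogenetic statistics (`cytostats`)

Location records carry a pattern (c = clustered, nc = cytologically
invisible, t = telomeric) and, on B chromosomes, per-arm region sets
(p/q arms; pe pericentromeric, i interstitial, t terminal, d distal). A
satellite on a B is *symmetric* when its region classes on the p and q
arms match, with pericentromeric signal ignored (arm-neutral) and
terminal/distal merged into a single arm-end class — both codes denote
the far end of an arm, and the published per-satellite symmetry scores
treat a t/d pair as matching. The symmetry index of a B chromosome is
the mean indicator over its non-pericentromeric satellites; a high SI is
the signature of a young isochromosome. One location cell of the
transcribed B table (ApaSat13-22 on BbM) was restored to `p:t;q:t`: the
extracted text dropped the p-arm token, while the published per-row
score and the figure caption both record that satellite as symmetric.

The test battery wraps scipy where scipy is exact for the published
conventions: Shapiro-Wilk (Royston), Spearman via midranks with the
t-approximation P, Levene mean-centred (df = 1, n−2), Fisher exact
(probability-mass two-sided; one-sided tails available — the published
shared-clusters P corresponds to the upper tail). Mann-Whitney reports
U = min(U1, U2) with midranks for ties; its exact two-sided P comes from
an own dynamic programme over tie groups (scipy's exact method refuses
ties), used whenever n·m ≤ 10,000, and is cross-checked against
exhaustive enumeration and scipy in the tests. Group summaries use the
sample (n−1) variance; the telomeric satellite is excluded from the
clustered/non-clustered dichotomy (reproducing n = 30 vs 5, df = 33).

## Pipeline and problem sizes

`pipeline.run` chains simulate → mine → group → quantify → compare →
cytogenetic summaries under one master seed and writes a manifest
(seed, config hash, stage log) sufficient to reproduce outputs
byte-identically. The bundled scenarios are sized for a single CPU:

* demo config — 50 kb A complement, 3 shared families + 1 B-restricted,
  2 × 30–40k pairs; runs in ~20 s.
* ten-family benchmark (`example_satellitome`) — 1.2 Mb A complement,
  RUL 18–365 bp, abundances 0.01–5%, 2 × 80k pairs, mining from 1000
  pairs doubling to 64k; the two rarest families sit at the detection
  floor by design and the acceptance bar is ≥ 8/10 recovered.
* dilution check — one A-only family at ~20% of a 200 kb genome,
  2 × 1M pairs; the 0B→1B relative abundance decrease lands within
  0.5 pp of the analytic 3.85% bound. The high family fraction keeps the
  binomial noise of the measured ratio well inside that band at this
  depth.

## Known limitations

* Discovery assumes monomers up to ~400 bp and arrays long enough that
  several reads fit inside; very short arrays (under ~2 read lengths)
  are invisible to clustering regardless of depth.
* Greedy overlap assembly tolerates intra-family divergence up to
  roughly 10%; beyond that, long-period consensus building degrades
  (short-period voting is unaffected).
* The identity metric's rotation/gap maximisation makes sub-60% values
  uninformative for short monomers; superfamily calls below the chance
  ceiling are suppressed rather than reported with a confidence.
* Abundance counts whole matched segments (read or half-read), so
  array-boundary reads contribute a small positive bias that cancels in
  0B/1B ratios but can overstate tiny absolute abundances.
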