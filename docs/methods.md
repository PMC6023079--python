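# Methods

This note documents the models, parameter choices and numerical
conventions behind `otukit`, and what its synthetic-data tests do and do
not demonstrate about real amplicon data.

## Read model and cleanup

Reads are single-end (forward-only) 16S amplicons whose first
`spacer_length` bases (default 4) are a degenerate heterogeneity spacer
added during library construction; the spacer is removed unconditionally,
whatever its letters. Cleanup then applies three per-read filters, in a
fixed order that determines the single rejection reason recorded per read:

1. **ambiguity** — any non-A/C/G/T base after spacer removal;
2. **low_quality** — any base with Phred quality < `min_quality`
   (default 20). This is a hard per-base filter, not sliding-window
   trimming: it is stricter, fully reproducible, and needs no window
   parameters;
3. **too_short** — post-trim length < `min_length` (default 240 nt).

Quality filtering runs after spacer removal, so a low-quality base inside
the (discarded) spacer never rejects a read. With `spacer_length=0` the
operation is idempotent. Dereplication groups exact strings and orders the
result by total abundance descending, ties broken lexicographically — the
deterministic order the clusterer consumes.

## OTU clustering

Clustering is a single greedy pass over the abundance-sorted uniques at an
identity radius of 0.97. Identity is computed from an edit-distance-optimal
global (Needleman–Wunsch) alignment, via `edlib`, as matches divided by
alignment columns with terminal gaps counted in the denominator; a
`matched_columns` dialect (gap columns excluded) is available because
tools differ on this convention. Because co-optimal alignments can differ
in gap placement, arguments are canonically ordered before alignment so
identity is exactly symmetric.

Uniques below `min_unique_size` (default 2) neither found nor join
clusters — singletons are likely error sequences — but every cleaned read
is mapped back to the accepted centroids afterwards (best identity ≥ 0.97,
ties to the earliest-founded OTU), so singleton reads are recaptured in
the count table and read totals are conserved per site (mapped + unmapped
= cleaned). Chimera detection is deliberately out of scope; the simulator
produces none, and real-data users should chimera-filter upstream.

Tie-breaking is fixed everywhere (abundance desc, then lexicographic
sequence, then founding order), making clustering a pure function of the
input multiset.

## LCA classification from BLAST-tabular hits

Per query the hit list is reduced in three stages.

*Thresholds.* The 100-hit cap is applied first (by bit score; ties by
lower E-value, then subject id), then the absolute thresholds — E-value
≤ 1e-15, percent identity ≥ 95.5, bit score ≥ 200, all inclusive — and
finally the relative band: bit score ≥ 0.99 × the best bit score **among
capped hits that passed the absolute thresholds**. Measuring the band
against the best *passing* hit prevents a high-scoring but low-identity
alignment from suppressing every usable hit; a `raw-best` reading would
conflate the two filters.

*Uninformative subjects.* Database entries named "uncultured",
"unclassified", "unidentified", "environmental sample" or "metagenome"
(case-insensitive, configurable) carry no taxon below high ranks. If at
least one retained hit is informative, all uninformative hits are dropped;
if none is, all are kept and the result is flagged `uncultured_only` and
reported under the `uncultured` category at ranks below the assignment.

*Majority LCA.* Hits are tallied per subject taxon (taxon id when
present, else name). The least frequent taxon is removed — ties broken by
removing the lexicographically last name — as long as the survivors still
account for ≥ 95% of the **original** retained-hit count, then the LCA of
the survivors is assigned. Measuring against the original count, and
removing one taxon at a time by frequency, is one of several readings of
a "most frequent taxa covering ≥ 95% of hits" rule; this greedy reading is
pinned by tests (including a brute-force re-implementation) so the
behaviour cannot drift silently. With the majority fraction at 1.0 and
skipping disabled the classifier reduces exactly to the plain LCA of all
threshold-passing hits.

Ranks deeper than the assigned node are labelled `unclassified`
(`uncultured` for `uncultured_only` results); these two categories are kept
distinct throughout profiling because they answer different questions
(a known clade with unresolved genus vs. environmental-clone-only
evidence).

## Diversity, rarefaction, shared OTUs

The Simpson index uses the finite-sample convention
D = Σ nᵢ(nᵢ−1)/(N(N−1)) — the probability that two reads drawn without
replacement belong to the same OTU — with inverse Simpson 1/D as the
effective OTU count and evenness defined as (1/D)/sobs. This evenness
definition is the ratio form consistent with reporting richness and
inverse Simpson side by side; on very small inputs it can exceed 1, in
which case the report carries a flag rather than clamping the value.

Rarefaction subsamples without replacement (multivariate hypergeometric;
`numpy.random.Generator`). The analytic expected-richness curve
E[sobs at d] = Σᵢ (1 − C(N−nᵢ, d)/C(N, d)) is evaluated with log-gamma
binomials to avoid overflow, and is cross-checked against Monte-Carlo
resampling in the tests. Normalization across sites, when requested, is
rarefaction to the smallest site depth at a fixed seed; diversity can be
computed on raw or normalized counts, as both conventions are in use.

Three-site shared-OTU structure is reported as the exact 7-region Venn
partition plus derived percentages (integer-rounded in the narrative
totals, 1 dp for pairwise cells, matching common reporting precision).
Pairwise shared percentages use the sum-of-richness denominator
100·|A∩B|/(|A|+|B|), so two identical sites share 50%, not 100%. The
linear identities relating regions to per-site richness are asserted on
every computation.

## Profiles

Rank profiles divide each taxon's per-site read count by the site total
and report the **unweighted mean** of per-site percentages as the average
— not the pooled-sequence fraction; the two differ when site depths
differ, and the unweighted mean is the convention the profile tables
follow (verified arithmetically in the tests). Taxa below the pooling
threshold (default 1%) in *every* site may be pooled as `other`; the
`uncultured`/`unclassified` pseudo-rows are never pooled. Output precision
is configurable rather than fixed per cell.

## Isolate comparison

Full-length isolate sequences are trimmed to the amplified region by
sliding-window minimal-mismatch search for the forward primer and the
reverse complement of the reverse primer (IUPAC degeneracy matches
compatible bases at zero cost; earliest position wins ties; primers are
excluded from the fragment). Extraction fails loudly when the best
placement exceeds the mismatch budget. The shipped example primers are
synthetic placeholders, not biological primer sequences — real analyses
must supply their own pair.

Co-clustering seeds OTU centroids first (abundance order) and isolates
second (lexicographic), so isolates attach to OTUs rather than founding
clusters that would absorb them; an isolate is "matched" when its cluster
contains an OTU. Phylogenetic tree inference over the co-clustered set is
out of scope; the module writes the region-trimmed FASTA for external
alignment/tree tools.

## Synthetic data generator

The generator emulates a three-site, multi-genus amplicon survey:

- **Taxonomy** — complete domain→genus paths, a configurable fraction of
  genera bearing uninformative names.
- **Reference database** — one random amplicon per genus (default 280 nt;
  i.i.d. random sequences put inter-genus divergence far above the 3% OTU
  radius), optional near-identical variants (0.5% divergence) and
  "uncultured bacterium" decoy entries byte-identical to an informative
  amplicon, attached to an unranked environmental node — the configuration
  in which skipping uninformative hits is decisive.
- **Communities** — log-normal genus abundances renormalized to 1,
  matching the long-tailed shape of real genus tables; an optional floor
  keeps every genus detectable in small runs.
- **Reads** — spacer + amplicon with i.i.d. substitutions (default run
  condition 1%, below the OTU radius), qualities uniform in
  [floor, 40], optional injected low-quality bases and ambiguities.
- **Hit tables** — per OTU × reference: identity from the same global
  alignment definition, a simple monotone bit score
  max(0, 2·matches − 3·non-matches) and E-value K·mn·2^(−bit) with fixed
  K = 0.1, mn = 10⁶. Only ordering and threshold behaviour matter
  downstream, so Karlin–Altschul statistics are not modelled.
- **Venn-constrained tables** — OTU × 3-site tables realizing any 7-region
  specification exactly, abundances ≥ 1.

All generators are pure functions of (parameters, seed), and truth
sidecars cover every generated read.

What passing synthetic tests does **not** show: robustness to indels,
chimeras, PCR bias, quality trajectories, primer mismatch within reads, or
reference databases whose entries diverge by less than the OTU radius.
Real communities also blur the clean genus separation simulated here;
recovery rates on real data will be lower than the synthetic 100%.

## Default run conditions

The end-to-end run (`run_synthetic_pipeline`) uses 10 genera spread over
three sites with Venn regions (1, 1, 2, 1, 1, 1, 3), 3,000 reads per site,
1% substitution error, an abundance floor of 8%, reference variants ×3 and
uncultured decoys on 30% of genera. These sizes give every present genus
several hundred reads — enough that the error-free amplicon dominates its
dereplicated uniques — while keeping a full run in seconds.

## Known limitations

- Identity is defined on one edit-distance-optimal alignment; alignments
  that would maximize matches at equal distance are not searched.
- The LCA majority rule's removal order among tied taxa is a pinned
  convention, not a community standard.
- Venn analysis is fixed at exactly three sites.
- No paired-end merging and no reverse-read use, by design.
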