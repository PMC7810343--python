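# Methods

## Scope and model of operation

rfamkit is a client: the covariance-model homology search itself runs on
the Rfam service (Infernal `cmscan` against the Rfam CM library). What the
package contributes is everything around that remote scan — query
fragmentation and coordinate bookkeeping for sequences beyond the service's
10,000-nt limit, asynchronous job orchestration, post-processing of hits
(deduplication, clan competition), and conversion of family data into
standard formats. Consequently all statements below concern client-side
behavior; hit *content* is whatever the service (or the replay store)
returns.

## Coordinates and hit normalization

All coordinates are 1-based inclusive, the convention Rfam itself prints.
Conversion to Python's 0-based half-open slices happens only inside
fragment extraction. The service reports reverse-strand hits with
start > end; these are normalized at ingestion to start ≤ end with
`strand = minus`, so every downstream interval computation (overlap,
dedup keys, sorting) is uniform. Hits on opposite strands never compete in
clan competition: sense and antisense elements are distinct annotations.

## Fragmentation

For a query of length L and window W (default 10,000 nt, the service
limit) with overlap v (default 3,000 nt), fragments start at
1, 1 + (W − v), 1 + 2(W − v), …; every fragment spans W positions except
the last, which ends exactly at L. This guarantees (i) full coverage of
[1, L], (ii) exactly v shared positions between consecutive fragments, and
(iii) a final fragment never shorter than v + 1 — so no degenerate tail
windows arise. v must exceed the longest hit one expects; a motif longer
than v that straddles a boundary would be truncated in both neighboring
fragments. 3,000 nt is comfortable for Rfam families (the longest hits in
the bundled case study span 353 nt).

Duplicate detection after remapping uses exact-key equality
(accession, start, end, strand), keeping the lower e-value. Near-duplicates
with shifted boundaries (conceivable when a hit is truncated at a fragment
edge) are deliberately not merged here — that is a biological-redundancy
question, which clan competition answers; dedup stays a conservative,
auditable coordinate operation.

A failure of any fragment's search aborts the whole query with an error
rather than returning partial results: a silently missing genome region is
worse than a loud failure.

## Clan competition

Two hits compete when their families share a clan, they lie on the same
strand, and their overlap is at least a threshold fraction t (default 0.5)
of the **shorter** hit; the worse hit of a competing pair is discarded.
Ranking is total: e-value ascending, then bit score descending, then
accession and coordinates. "Worse" is evaluated pairwise against the whole
input — a hit is discarded iff *some* strictly better-ranked hit competes
with it, whether or not that better hit itself survives. The alternative
(comparing only against surviving hits) introduces removal cascades in
overlap chains A–B–C, which makes the retained set non-monotone in the
threshold and harder to reason about; the pairwise rule is cascade-free,
idempotent, permutation-invariant, monotone in t, and identical on every
realistic configuration where competing hits overlap transitively (as in
the bundled case study, where both rules retain the same three hits).
Families absent from the clan table never compete.

The clan table ships as a small bundled snapshot (TSV, family → clan)
covering the fixture families; `rfamkit refresh-clans` rewrites it from
the live service.

## Transport, polling, replay

Every remote operation is an `EndpointRequest` (endpoint kind + target +
parameters) served by a backend. The live backend uses stdlib HTTP with a
minimum 1-s spacing between search submissions, politeness toward a public
service. Transient failures are retried up to 3 times with exponential
backoff (1 s, ×2); job polling starts at 5 s and grows ×1.5 to a 60-s cap,
with a 10-min default per-fragment timeout — the schedule is monotonically
non-decreasing by construction.

The replay backend serves recorded responses from disk, keyed by a
canonical request digest (kind + target + sorted params, with sequences
replaced by their SHA-256). Replay mode performs zero network operations;
an unrecorded request is an error. Poll entries may record a
pending → done sequence; once done, the payload never changes. Recorded
404s surface as typed not-found errors, so offline behavior matches live
behavior for missing families.

## Formats

* **Stockholm** — parsed and written losslessly against the alignment data
  model (rows, GC column annotations, GR per-row annotations, GF/GS file
  annotations), including interleaved multi-block records. A generic
  reader that canonicalizes annotation keys would break round-tripping,
  which the toolkit guarantees; Biopython's reader serves as an
  independent cross-check on sequence content in the tests.
* **FASTA dialects** — `fasta` keeps gapped rows verbatim; `fastau`
  removes both gap characters (`-` and `.`, the latter being Rfam's
  insert-state marker). `pfam` is single-block Stockholm with the
  consensus-structure line rewritten in dot-bracket.
* **WUSS → extended dot-bracket** — unpaired symbol classes
  (`:`, `,`, `_`, `-`, `~`, `.`) map to `.`; the four bracket families and
  pseudoknot letter pairs are preserved as distinct families (Rfam's own
  extended dot-bracket output mixes bracket families, so flattening to
  `()` would lose information). The conversion preserves length and the
  exact base-pair map, validated per family with independent stacks.
* **NHX trees** — parsed with dendropy, NHX comment blocks kept opaque.
  The root counts as internal iff it has ≥ 2 children, so a fully resolved
  unrooted tree with n tips has n − 2 internal nodes and a strictly
  bifurcating rooted tree n − 1.
* **Covariance models and SVG** — validated (Infernal header token; XML
  `<svg>` root) and passed through byte-identically; parsing their
  internals is out of scope.
* **TSV exports** — tabs/newlines/backslashes in fields are
  backslash-escaped so rows stay one-line and round-trip.

## Synthetic data

The generator plants literal RNA motifs (≥ 20 nt, default 24–40 nt) at
non-overlapping random positions in a random background genome, then
records per-fragment search responses listing exactly the motif
occurrences each fragment fully contains — an exact-match stand-in for the
server-side covariance-model scan. Ground truth is re-derived by scanning
the final genome, so it is exact by construction. This emulates the
*coordinate bookkeeping* problem (boundary-spanning motifs, duplicated
motifs, overlap-region double reporting) but none of the statistical
character of real CM hits: no alignment scores shaped by a model, no
partial/degraded matches, no strand complexity. Passing recovery tests
therefore validates orchestration and coordinate arithmetic, not homology
detection sensitivity — which is the service's job, not the client's.

The case-study fixture reconstructs a whole-genome annotation run on a
29,903-nt betacoronavirus genome: seven hits (the generic and
SARS-specific 5′-UTR pair, the frameshifting element, and the 3′-UTR group
with its nested pseudoknot and s2m motifs), two clans, and e-values drawn
log-uniform (10⁻⁷⁰–10⁻⁸) and then assigned so the SARS-specific hit ranks
best within each clan — the documented outcome of such a run. The genome
itself is synthetic (random background, fixed internal seed 20903); hit
coordinates are recorded in the replay store rather than planted, since
two families annotate the identical 5′ interval. Every payload in the
store (consensus structure, 19-row seed alignment, 19-tip unrooted tree,
covariance model, SVG) is a synthetic stand-in with the correct shape and
format, generated deterministically.

## Problem sizes in the test suite

Property suites run at: 1,000 random instances (≤ 8 hits each) against the
subset-enumeration clan-competition oracle; 500 random
(length, window, overlap) triples for fragment-cover reconstruction; 200
random alignments for Stockholm round-trip; 200 random balanced structures
for WUSS conversion; 300 instances each for dedup and filter-invariant
suites; and 20 seeded synthetic worlds (25,000-nt genomes) for exact
ground-truth recovery. The full suite completes in a few seconds on one
CPU.

## Known limitations

* The live HTTP backend's URL scheme follows the public REST interface but
  is exercised only through the replay contract in the test suite; a
  service-side interface change would surface on first live use, not in
  tests.
* The `pfam` dialect is pinned by this package's convention (single-block,
  dot-bracket structure line), not by a service-recorded fixture.
* Ambiguity codes (IUPAC) are accepted and forwarded, but their handling
  by the remote scan is the service's behavior, not modeled here.
* Clan competition assumes coordinate-normalized hits; it never rescores
  alignments or competes across clans.
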