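# rfamkit

A Python client toolkit for the [Rfam](https://rfam.org) database of
non-coding RNA families, aimed at genomic workflows that need programmatic —
rather than interactive — access to Rfam: annotating whole genomes with
non-coding RNA elements, and pulling family data (summaries, consensus
secondary structures, seed alignments, covariance models, phylogenetic
trees, member regions, PDB mappings) into standard bioinformatics formats.

Every remote interaction sits behind a replayable transport: the same
pipeline runs against the live REST service or against an on-disk store of
recorded responses, so analyses are reproducible and the entire test suite
runs offline.

## What it computes

**Unlimited-length sequence search.** The Rfam search endpoint accepts at
most *W* = 10,000 nt per query. For a query of length *L* > *W*, rfamkit
splits it into overlapping fragments starting at 1, 1 + (*W* − *v*),
1 + 2(*W* − *v*), … with overlap *v* (default 3,000 nt), searches each
fragment as its own job, and maps each fragment-local hit (s, e) back to
parent coordinates (s + start − 1, e + start − 1). Hits reported
identically by two fragments of the overlap region are collapsed, keeping
the lower e-value. The overlap should exceed the longest expected hit so
any motif straddling a boundary is seen whole by at least one fragment.

**Clan competition.** Rfam groups related families into clans; same-clan
hits on the same region are redundant annotations. For hits *a*, *b* with
intervals [s<sub>a</sub>, e<sub>a</sub>], [s<sub>b</sub>, e<sub>b</sub>],
define the overlap fraction

&nbsp;&nbsp;&nbsp;&nbsp;f(a,b) = max(0, min(e<sub>a</sub>,e<sub>b</sub>) − max(s<sub>a</sub>,s<sub>b</sub>) + 1) ⁄ min(|a|, |b|),

i.e. overlap length as a fraction of the **shorter** hit. A hit is
discarded iff some strictly better hit of the same clan and strand has
f ≥ t (default t = 0.5). Ranking is by ascending e-value, then descending
bit score, then accession — a total order, so the result is independent of
input order. Disabling the filter keeps nested hits visible.

## Worked example

The bundled case-study fixture replays a whole-genome annotation run on a
29,903-nt betacoronavirus genome (synthetic sequence; real annotation
layout). From a shell:

```bash
python - <<'EOF'
from rfamkit import RfamClient, SearchOptions
from rfamkit.fixtures import build_case_study

fx = build_case_study("scratch/casestudy")
client = RfamClient.for_replay(fx.store.directory, clans=fx.clans)

for filt in (False, True):
    hits = client.sequence_search(
        fx.genome, SearchOptions(fragments_overlap=3000, clan_competition_filter=filt))
    print(f"clan competition {'on ' if filt else 'off'}: {len(hits)} hits")
    for h in hits:
        print(f"  {h.rfam_id:<20}{h.query_start:>6}{h.query_end:>8}")
EOF
```

prints

```
clan competition off: 7 hits
  bCoV-5UTR                2     300
  Sarbecovirus-5UTR        2     300
  Corona_FSE           13470   13551
  bCoV-3UTR            29519   29871
  Sarbecovirus-3UTR    29537   29871
  Corona_pk3           29604   29663
  s2m                  29728   29770
clan competition on : 3 hits
  Sarbecovirus-5UTR        2     300
  Corona_FSE           13470   13551
  Sarbecovirus-3UTR    29537   29871
```

Without the filter, all seven non-coding RNA elements are reported,
including the nested/duplicated ones: both the generic betacoronavirus and
the SARS-specific versions of each UTR, plus the pseudoknot (Corona_pk3)
and s2m motifs contained inside the 3′-UTR. With clan competition, each
clan keeps only its best-scoring hit, leaving the SARS-specific UTRs and
the (unclanned) frameshifting element.

The same run is available from the command line:

```bash
rfamkit --offline --replay-dir scratch/casestudy \
    search-sequence genome.fasta --overlap 3000 --no-clan-filter
```

Family-data retrieval works the same way (`rfamkit summary RF00005`,
`rfamkit structure RF03120 --format DB`, `rfamkit seed-alignment RF03120
--format fastau`, `rfamkit seed-tree RF03120`, …); drop `--offline` to use
the live service.

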