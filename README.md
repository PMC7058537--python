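# tadsv

Analysis of topologically associating domain (TAD) disruption by somatic
structural variants (SVs) in cancer genomes.

Chromatin is folded into TADs — regions of enriched internal Hi-C contact —
separated by insulating boundaries. Somatic rearrangements that delete,
duplicate or invert across a boundary can fuse neighboring domains and
rewire enhancer–promoter contacts. `tadsv` implements the full desk-scale
pipeline for studying this process in SV cohorts:

1. **Boundary calling** — insulation score I(i): the mean contact frequency
   in a square window (default 1 Mb per side at 25-kb bins) sliding along
   the matrix diagonal, log2-normalized per chromosome; boundaries are local
   insulation minima, detected as upward zero crossings of a delta track
   (mean score over the next 200 kb minus the previous 200 kb), filtered by
   a strength threshold and emitted as 3-bin (75-kb) intervals.
2. **Consensus boundaries** across cell types: boundaries of every input set
   grouped within 50 kb.
3. **Boundary-affecting (BA) SVs** — a short-range (< 2 Mb) SV is BA when
   its footprint fully contains a boundary interval. Enrichment per SV type
   is measured against a bootstrap null of shuffled boundaries (placement
   uniform per chromosome, counts preserved), reporting fold
   (observed / null mean), z, and empirical p.
4. **Domain annotation** — domains between consensus boundaries carry a
   15-state chromatin coverage vector and are k-means-clustered (k = 5) into
   heterochromatin / low / repressed / low-active / active classes, with
   per-class expression summaries, flanking-domain pairs of BA-SVs, and
   LAD / inter-LAD overlap statistics.
5. **Expression fold changes** — for each BA-SV, the nearest non-overlapping
   genes up/downstream of the break-ends; fc = expression in the carrier
   sample over the mean of the remaining cohort, filtered for low expression
   (< 0.1 FPKM), amplified copy number (> 4) and distance (> 1 Mb); groups
   compared with one-tailed Mann–Whitney U tests.
6. **TAD fusion statistics** — distance-decay expected contacts, per-SV
   ploidy scaling factors (< 0.1 flags unsupported calls), intra- vs
   inter-TAD/SV contact classification around each SV, and aggregate
   break-end contact enrichment.

A first-class synthetic-data module generates every input (block-TAD contact
maps with power-law decay, cohort SV catalogs, state/LAD tracks, expression
and copy-number tables) with known ground truth, so the whole pipeline is
testable without external downloads.

## Worked example

```python
from tadsv import (PipelineConfig, call_boundaries, insulation_profile,
                   ba_enrichment)
from tadsv.synthetic import (GenomeSpec, CohortSpec, plant_boundaries,
                             simulate_hic, simulate_sv_catalog)

spec = GenomeSpec({"chr1": 20_000_000}, 25_000)
truth = plant_boundaries(spec)              # 9 boundaries, one per 2 Mb
mat = simulate_hic(spec, truth, tau=1.0, depth=60, seed=1)["chr1"]

cfg = PipelineConfig()
called = call_boundaries(insulation_profile(mat, cfg), cfg, source="toy")

svs, _ = simulate_sv_catalog(spec, CohortSpec(n_samples=40), called,
                             enrichment_knob={"DUP": 0.4}, seed=2)
enr = ba_enrichment(svs, called, spec.chrom_sizes, n_shuffles=1000, seed=3)
for t, (frac, res) in enr.items():
    print(f"{t}: BA fraction {frac:.3f}  fold {res.fold:.2f}  "
          f"z {res.z:+.2f}  empirical p {res.p_empirical:.4f}")
```

prints

```
COMPLEX: BA fraction 0.250  fold 1.17  z +0.56  empirical p 0.3866
DEL: BA fraction 0.202  fold 1.14  z +0.72  empirical p 0.2787
DUP: BA fraction 0.567  fold 3.25  z +9.58  empirical p 0.0010
INV: BA fraction 0.222  fold 1.28  z +1.09  empirical p 0.1748
```

All nine planted boundaries are recovered, and only the duplication channel
— where 40% of events were forced to span a boundary — shows significant
enrichment over the shuffled-boundary null; the uniformly placed deletion,
inversion and complex events sit at chance levels.

## Command line

```sh
tadsv simulate --out bundle/ --seed 1 --enrichment-knob 0.3
tadsv run-all --bundle bundle/ --out results/ --seed 1 --n-shuffles 1000
```

`simulate` writes a complete plain-text input bundle (COO contact matrices +
bin tables, SV/gene/state/LAD BED and TSV files, expression and copy-number
tables) plus the ground truth; `run-all` executes boundaries → consensus →
sv → domains → expression → fusion, writing TSV/BED outputs and a manifest
with input digests. Individual stages are available as subcommands
(`call-boundaries`, `consensus`, `classify-sv`, `enrich`,
`annotate-domains`, `expression-fc`, `fusion`). Runs are byte-identical for
a fixed seed.

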