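# epimeta

Downstream analytics for m⁶A RIP-seq and ChIP-seq experiments, plus the
kinetic/pharmacological models that typically accompany them:

- **annotation** — GTF parsing, longest-isoform selection, and a composite
  metagene coordinate system (1 kb flank / 5′UTR / CDS / 3′UTR / 1 kb flank)
  with strand-aware spliced projection of genomic positions.
- **spikein** — per-batch scaling factors from exogenous spike-in read counts
  (ratio to the batch minimum) and deterministic or binomial-thinning
  downscaling of count/coverage signal.
- **peaks** — BED/narrowPeak I/O, summit-anchored peak annotation to genomic
  features (promoter > 5′UTR > 3′UTR > CDS > intron > TTS > intergenic),
  peaks-per-gene burdens, m⁶A-positive gene sets, a permutation test for peak
  count differences, DEG filtering (|log2FC| > 1, padj < 0.01) and gene-set
  (Venn) intersection.
- **metagene** — projection of peak sets into metagene coordinates and
  cross-condition relative density profiles in which each condition's area is
  proportional to its peak count and all areas sum to 1.
- **chip** — interval overlap partitions (co-binding Venn logic),
  promoter-bound gene sets, per-gene peak-burden comparisons (Mann–Whitney),
  and anchor-centered binned signal matrices from bedGraph coverage.
- **response** — one-phase exponential decay fits (t½ = ln 2 / k), 4PL
  dose–response fits, Loewe additivity reference surfaces solved per cell by
  bisection of the isobole equation, and synergy scoring/classification
  (> 10 synergistic, −10..10 additive, < −10 antagonistic).
- **simulate** — seed-deterministic synthetic GTF / narrowPeak / bedGraph /
  TSV fixtures with planted ground truth for every stage.

## CLI

All functionality is exposed through the `epimeta` command:

```bash
# generate a full synthetic dataset with ground-truth sidecars
epimeta simulate all --seed 7 --out demo/

# build the annotation + metagene model
epimeta annotation build --gtf demo/annotation.gtf --out demo/model.json \
    --bins 100,100,100 --flank 1000

# spike-in scaling factors
epimeta spikein --counts spikes.tsv --out factors.tsv

# peak analytics
epimeta peaks annotate --peaks demo/peaks.condA.narrowPeak --model demo/model.json --out ann.tsv
epimeta peaks burden   --peaks demo/peaks.condA.narrowPeak --model demo/model.json --out burden.tsv
epimeta peaks permtest --peaks-a demo/peaks.condA.narrowPeak --peaks-b demo/peaks.condB.narrowPeak --n-perm 1000 --seed 1
epimeta peaks deg-overlap --de demo/de_table.tsv --genes burden.tsv --lfc 1 --padj 0.01

# metagene relative density across conditions
epimeta metagene --peaks demo/peaks.condA.narrowPeak:condA \
    --peaks demo/peaks.condB.narrowPeak:condB \
    --model demo/model.json --out profile.tsv --plot profile.png

# ChIP integration
epimeta chip overlap --peaks-a demo/peaks.factorA.narrowPeak --peaks-b demo/peaks.factorB.narrowPeak
epimeta chip promoters --peaks demo/peaks.factorA.narrowPeak --model demo/model.json
epimeta chip matrix --track demo/coverage.factorA.bedGraph --anchors anchors.bed --flank 4000 --bin-width 50 --out matrix.tsv

# decay kinetics and drug synergy
epimeta decay fit --table demo/decay.tsv
epimeta synergy score --matrix demo/dose_matrix.tsv --model loewe
```

## Conventions

Internal coordinates are 0-based half-open everywhere; GTF is read as 1-based
inclusive and BED/narrowPeak/bedGraph as 0-based half-open. Peaks are anchored
at their summit when present, otherwise at the interval midpoint. "Longest
isoform" means maximal summed exon length with lexicographic transcript-id
tie-break.
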