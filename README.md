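# blastxy

Browse massive BLAST result sets against multi-replicon bacterial and
archaeal genomes as a single interactive *x, y* plot.

Comparative searches — "where does this gene cluster occur across a whole
genus?" — routinely produce tens of thousands of BLAST hits spread over
chromosomes and plasmids of wildly different sizes. `blastxy` makes them
browsable by projecting every circular replicon onto a straight line of
fixed length **360** (the degrees of a circle): a hit at nucleotide
position *p* of a length-*L* replicon is drawn at its *relative position*

    x = 360 · (p − 1) / L        (degrees, 0 ≤ x ≤ 360)

and at *y* = the replicon's index (1 … N) in the job. On this plane each
hit is rendered as

- a **dot** at the strand-aware origin of the subject gene,
- a **vector** whose magnitude is the gene length in degrees and whose
  direction is the transcription sense,
- a **thicker alignment segment** over the vector, spanning the aligned
  region of the subject, colored by the BLAST **BitScore** from dark blue
  (most significant) down to yellow (least significant).

Because the axis is relative, operon-like gene clusters show up as tight
runs of nearby hits regardless of genome size, and conserved loci can be
compared across hundreds of replicons at once. The result table supports
spreadsheet-style sorting and case-sensitive "contains" filtering (AND
composition across columns), with a display cap of 50 000 rendered
results and a raw export cap of 1 000 000.

Intended users: microbial comparative genomicists screening for gene
clusters (bacteriocin loci, secretion systems, biosynthetic pathways)
across many sequenced genomes.

## Worked example

Simulate two organisms (chromosome + plasmid each) with a planted
four-gene bacteriocin-style locus hit by queries `capA`–`capD`, then run
a job:

```sh
blastxy simulate \
  --genome-spec '{"n_organisms": 2, "replicon_lengths": [400000, 60000],
    "genes_per_replicon": 50,
    "organism_names": ["Burkholderia_synthetica", "Synthetica_minor"],
    "cluster_tags": [["Burkholderia_synthetica_rep1", 10, 4, "capistruin-like"]]}' \
  --hit-spec '{"queries": ["capA", "capB", "capC", "capD"], "hit_rate": 0.5,
    "planted_clusters": [{"replicon_id": "Burkholderia_synthetica_rep1",
      "start_gene_index": 10, "queries": ["capA", "capB", "capC", "capD"]}]}' \
  --seed 11 -o demo

blastxy run --title "Capistruin demo" --hits demo/hits.tsv \
  --gff demo/annotation.gff3 --replicons demo/replicons.tsv \
  --evalue 1.0 -o demo/job
```

which prints

```
demo: wrote demo/annotation.gff3, demo/replicons.tsv, demo/hits.tsv (planted=4 background=10)
demo/job: parsed=14 resolved=14 unresolved=0 filtered=14 displayed=14
```

The job folder contains `Capistruin_demo_Sorted.tsv` (all capped results,
most significant first), `Capistruin_demo_Sorted_Scored.tsv` (rows
surviving the active filters), the results JSON, the interactive
`graph.html` (zoom/drag main panel, x- and y-overview range selectors,
hover and click detail), a static `graph.svg` and a sortable/filterable
`table.html`. Proximity clustering on the same results:

```python
from blastxy import formats, projection, results

hits = formats.read_blast_tabular("demo/hits.tsv")
reps, feats = formats.read_annotation("demo/annotation.gff3", "demo/replicons.tsv")
reps = projection.assign_replicon_indices(reps)
rows, unresolved = projection.project_hits(hits, feats, reps)
big = max(results.detect_clusters(rows), key=len)
```

prints, via the obvious report loop:

```
14 results on 4 replicons; 11 clusters
largest cluster: 4 hits on Burkholderia_synthetica_rep1 at 81.7-84.7 degrees
  capA  x=81.733  y=1  vector=+1.127  bitscore=235.9
  capB  x=82.882  y=1  vector=+0.790  bitscore=334.1
  capC  x=84.642  y=1  vector=-0.948  bitscore=200.6
  capD  x=84.665  y=1  vector=+0.782  bitscore=251.6
```

— the planted four-gene locus comes back as one tight cluster spanning
three degrees of the chromosome: four hits at consecutive relative
positions on track *y* = 1, `capC` on the minus strand (negative
vector), each colored by its bitscore. `x` is the transcription start of
each subject gene in degrees; the vector magnitude is the gene length on
the 360 axis.

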