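# cutfoot

Single-nucleotide cut-matrix estimation and probabilistic motif footprinting
for CUT&RUN-style paired-end cleavage data.

The pA-MN nuclease releases short DNA fragments whose two ends are cut
sites. `cutfoot` turns coordinate-level fragment data into:

- **strand-specific, motif-oriented cut matrices** at single-nucleotide
  resolution (sites × positions, ±flank around each motif occurrence, with
  minus-strand rows flipped into a common orientation and zero cut-site
  offset by default — ATAC-style offsets are available as a config pair);
- **a two-component bound/unbound mixture model** fitted by EM: a shared
  per-position cut-probability vector λ over `S = 2W` strand-specific
  positions for bound sites vs. a uniform profile for unbound sites, with
  negative-binomial read-total components, yielding a per-site posterior
  binding **log-odds**;
- **a footprint symmetry score (FSS)** from exponential fits to the two
  halves of the footprint profile (`FSS = B_left·R²_left − B_right·R²_right`),
  used to classify a motif as primary (the assayed factor's own site) or
  secondary (a co-factor);
- **direct binding-site calls**: primary motif + inside a retained peak
  (blacklist and chrM peaks removed) + log-odds strictly greater than 5;
- **a second-pass 3′ adapter-overhang trimmer** that removes exact
  1–6 bp read-through overhangs missed by template trimmers and applies a
  25-bp minimum-length pair filter;
- **QC metrics** (fragment-size histogram, ≤120-bp fraction, adapter loss,
  library size, duplication rate, alignment percentage, peak count, motif
  enrichment) with per-metric pass/warn flags and no single overall verdict;
- **a synthetic-data simulator** that generates fragments, motif sites,
  peaks, and adapter read-through FASTQ with known ground truth, so every
  stage is testable offline.

Alignment, peak calling, and motif scanning are out of scope: `cutfoot`
consumes aligned fragments (BAM/SAM or fragment BED), peak BED, and motif
occurrences as stranded BED6. All coordinates are 0-based half-open; cut
sites are inter-base boundaries (the forward cut of a fragment is its
`start`, the reverse cut its `end`, which also makes the reverse-strand
1-bp shift correction of naive base-anchored extraction unnecessary).

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence of the cut matrix against per-base enumeration, bamtobed-style
fragment parity, closed-form log-odds checks, EM monotonicity and parameter
recovery, FSS analytics, calling logic, trimmer truth on simulated
read-through FASTQ, QC arithmetic, and end-to-end determinism).

## CLI

Every stage is a subcommand; `run` chains them from a JSON config.

```sh
# synthetic dataset with ground truth
cutfoot simulate --out-dir sim --n-bound 300 --n-unbound 200 --seed 1

# full pipeline from a config
cat > config.json <<'EOF'
{
  "simulate": true,
  "sim_n_bound": 300,
  "sim_n_unbound": 200,
  "size_threshold": null,
  "assume_primary": true,
  "output_dir": "out",
  "seed": 1
}
EOF
cutfoot run --config config.json          # add --dry-run to see the plan

# individual stages
cutfoot trim --in1 R1.fastq.gz --in2 R2.fastq.gz --out1 t1.fastq.gz --out2 t2.fastq.gz
cutfoot fragments --input aligned.bam --out-prefix frags
cutfoot cutmatrix --fragments frags.le120.bed --sites motifs.bed --out-prefix cm
cutfoot footprint --fragments frags.le120.bed --sites motifs.bed --out-prefix fp
cutfoot fss --model fp.model.json --out fss.tsv
cutfoot call --scores fp.scores.tsv --sites motifs.bed --peaks peaks.bed --out-prefix calls
cutfoot qc --fragments frags.le120.bed --peaks peaks.bed --sites motifs.bed --out qc.json
cutfoot tracks --fragments frags.le120.bed --region chr1:72767100-72767300 --out-prefix cuts
```

For real data the typical flow is: template-trim + align externally (keep
dovetail pairs), `fragments` to extract and size-fractionate fragment
intervals, call peaks externally, scan motifs externally, then `cutmatrix`
→ `footprint` → `fss` → `call` → `qc` here.

Notes:

- `size_threshold` (default 120) keeps the ≤120-bp factor-scale fraction
  for footprinting; `null` disables fractionation. Simulated fragments are
  all window-sized, hence `null` in the example.
- Duplicate fragments (identical R1 start/R2 end/strand) are retained by
  default; `remove_duplicates` drops them.
- `assume_primary` overrides the FSS gate when the motif is known to be
  the assayed factor's own.

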