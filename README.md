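# mitoskew

Strand-asymmetry and translation-system analysis of annotated circular
mitochondrial genomes: skew statistics and comparative skew atlases,
circular sliding-window (G+T)/(A+C) profiles with replication-origin
inference, homopolymer-run censuses, codon-usage and amino-acid-composition
analysis, anticodon-versatility classification, and conservation-based
genetic-code assignment — plus a seeded synthetic-genome generator so every
stage is testable offline.

## Modules

| module | what it does |
| --- | --- |
| `mitoskew.genome_io` | GenBank/FASTA parsing and writing, circle-aware coordinates, main-strand normalization, feature extraction, unassigned-sequence (UAS) census |
| `mitoskew.composition` | base tallies, AT-skew `(A−T)/(A+T)` and GC-skew `(G−C)/(G+C)`, per-gene-class AT/GT content, region-restricted counts, homopolymer runs |
| `mitoskew.strand_profile` | per-position (G+T)/(A+C) ratio over a 300-base circular window (149 left / 150 right), OLS trend + shading, oriL/oriH inference, skew atlas with covariance ellipses |
| `mitoskew.codon_code` | genetic codes (NCBI tables 2/5/9/13 + the pterobranch variant with AUA→Ile, AGG→Lys), codon usage, amino-acid composition, GT/AC codon-class labels, wobble families, anticodon-versatility classification and deviation counting |
| `mitoskew.code_inference` | conservation-graded genetic-code assignment from aligned reference proteins (four degrees, configurable thresholds, anticodon/base-code fallbacks) |
| `mitoskew.synthetic` | deterministic annotated-genome generator: tunable strand bias, origin-centred gradients, planted homopolymer runs, codon sampling under any built-in code, truth records, reference-alignment simulator |
| `mitoskew.cli` | `mitoskew` command-line front end |

## CLI

```sh
mitoskew simulate --preset rhabdopleura-like --seed 7 --out-prefix g   # g.gb + g.truth.json
mitoskew compose g.gb                          # composition / skew report
mitoskew profile g.gb --origins-out ori.json   # ratio profile + origin calls
mitoskew codons g.gb --code rhabdopleura       # 64-row codon usage table
mitoskew pairing g.gb --code rhabdopleura      # versatility classes + deviation count
mitoskew uas g.gb --bed-out uas.bed            # unassigned regions
mitoskew atlas a.gb b.gb --groups groups.tsv   # comparative skew atlas
mitoskew infer-code g.gb --refs refdir/        # genetic-code assignment
mitoskew report g.gb --outdir out/             # full bundle + manifest
```

Presets: `rhabdopleura-like` (T-rich/G-rich main strand), `vertebrate-like`
(AC-rich), `unbiased`.

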