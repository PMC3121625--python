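# data/

Drop-in location for the deposited mitochondrial genome record used by the
accession-bound acceptance targets and tests.

The record is **FN908482** (a 15,814 bp circular mitochondrial genome).
It is not redistributed here and the analysis environment has no network
access, so the record-bound targets (t1–t9 in `scripts/acceptance.py`) and
the `TestDepositedRecord` acceptance tests activate only when the file is
present.

To enable them, fetch the flat file once from any INSDC mirror and save it
as `data/FN908482.gb`, e.g.:

```sh
curl -o data/FN908482.gb \
  "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=FN908482&rettype=gb&retmode=text"
```

Everything else in the package (all property suites, synthetic-data
parameter recovery, the CLI) is fully functional without this file.
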