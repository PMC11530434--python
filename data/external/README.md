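# External reference data (not redistributed)

Two groups of tests read real COSMIC reference data that cannot be
bundled with this repository. Place the files here to enable them:

- `COSMIC_v3_SBS_GRCh38.txt` — the COSMIC v3 SBS signature catalog for
  GRCh38 (67 signatures, tab-separated, first column `Type`), from
  https://cancer.sanger.ac.uk/signatures/downloads/
- `activities/<CancerType>.tsv` — per-sample signature activity tables
  derived from the COSMIC v3.2 tissue-contribution data
  (rows = samples, columns = signatures, absolute or relative weights);
  the tests use `Liver-HCC.tsv` and `ColoRect-AdenoCA.tsv`.

Without these files the corresponding checks in
`tests/test_acceptance.py` fail with a message pointing here; every
other test runs on synthetic fixtures generated at test time.
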