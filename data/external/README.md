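# External reference data

The published cytochrome *b* alignments for the two focal datasets are
not redistributable with this package. To run the full reference
checks in `tests/test_acceptance.py`, place the NEXUS alignments here:

- `bmajor_cytb.nex` — the *B. major* dataset (784 aligned sites; sample
  ids matching the `sample_id` column of
  `src/mitoibd/data/bmajor_samples.tsv`, e.g. `7a`, `i1`, `s4b`)
- `bnigriventris_cytb.nex` — the *B. nigriventris* dataset (ids
  matching `bnigriventris_samples.tsv`)

Both files are available as supplementary data of the original study;
the loaders tolerate the presence or absence of the excluded
population 17 row (it is dropped via the configured drop-list).
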