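# Real accession records (not shipped)

This directory is intentionally empty. The real-data checks in
`tests/test_acceptance.py` look here for the deposited honeybee
mitogenome GenBank records:

- `MW811175.gb` — *A. m. carnica*, Slovenia (SICarnica)
- `MN250878.gb` — *A. m. carnica*, Austria (ATCarnica)
- `NC_001566.gb` — *A. m. ligustica* reference (REFLigustica)
- `apis29.aln.fasta` — a user-built alignment of the 29-genome set
  for the ABGD six-group check

Populate it on a machine with network access:

    python scripts/fetch_accessions.py

Without these files the two real-data acceptance tests report failure;
every synthetic check runs regardless.
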