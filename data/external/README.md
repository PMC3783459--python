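# External data

Place the real deposited haplotype sequences here to enable the
distance-based checks on the worked dataset:

    spinner_nd4_haplotypes.fasta  — GenBank accessions KF612545-KF612581

See the "Reproducing the published results" section of the top-level
README for the one-command download. Files in this directory are
user-downloaded research data and are not redistributed with the package.
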