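# Deposited coordinate files

The acceptance checks that run on deposited crystal structures expect
PDB-format files in this directory (they are not redistributed with the
package):

- `3sgg.pdb` — the GxGYxYP-domain protein BT2193 from *Bacteroides
  thetaiotaomicron* (https://files.rcsb.org/download/3sgg.pdb)
- `1js4.pdb` — the GH9 cellulase whose Asp55/Asp58/Glu424 catalytic triad
  serves as the site template (https://files.rcsb.org/download/1js4.pdb)
- `gxgyxyp_family.fasta` — optional: a family multiple sequence alignment
  containing the BT2193 sequence, for the conserved-patch check.

All other tests are self-contained and need no downloads.
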