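# Reference crystal structures (user-supplied)

The validation suite and `scripts/acceptance.py` can check the package
against two reference protein–protein complexes:

| file       | complex                               | partner A (chain) | partner B (chain) |
|------------|---------------------------------------|-------------------|-------------------|
| `7cei.pdb` | ColE7 DNase domain – Im7 immunity protein | ColE7 (`A`)    | Im7 (`B`)         |
| `1qa9.pdb` | CD2 – CD58 adhesion domains           | CD2 (`A`)         | CD58 (`B`)        |

Structure files are not redistributed with this repository. To enable these
checks, download the entries from the Protein Data Bank and place them here
with lowercase names:

    curl -o 7cei.pdb https://files.rcsb.org/download/7CEI.pdb
    curl -o 1qa9.pdb https://files.rcsb.org/download/1QA9.pdb

Without the files the corresponding tests report a clear failure message,
and the acceptance script simply omits the crystal-structure quantities.
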