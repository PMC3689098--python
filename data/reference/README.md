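# Reference structures

The reference-data acceptance tests analyze the published helix-binding
complexes (calmodulin, centrin, BCL-XL, MDM2, troponin C). Those PDB entries
are not bundled with the package; place them here as uncompressed `.pdb`
files, e.g.:

```bash
helixsurf fetch 2O5G 1ZUZ 2VAY 3DVE 1QTX 2HQW 2GGM 2K2I 3KF9 1BXL 1YCR 1A2X \
    --out data/reference
```

For the sequence-identity checks, additionally provide `sequences.fasta`
with the crystallized-fragment sequences under ids starting with
`P62158` (human calmodulin), `P62149` (chicken calmodulin), `1QTX`
(the calmodulin-like chain of that entry), `P41208` (human centrin 2) and
`Q06827` (Scherffelia dubia centrin).

Without these files the corresponding tests fail with instructions; they
never pass vacuously and never download anything themselves.
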