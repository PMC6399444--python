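# data

Drop a local copy of the public E2-state crystal structure (PDB entry
2agv, from https://files.rcsb.org/download/2AGV.pdb) here as `2agv.pdb`
to enable the crystal worked value (the Gln108–Thr316 side-chain distance,
reference ≈ 0.65 nm) in the test suite and in `scripts/acceptance.py`.
The file is not bundled with the repository.
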