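Optional real-structure data
============================

`test_acceptance.py::TestDepositedStructureExample` checks the four-cysteine
structural-site placement against the zinc deposited in PDB entry 7lyt
(CasPhi-2 / Cas12j cryo-EM structure). The coordinates are not bundled;
download `7lyt.pdb` (or `7lyt.cif`) from the PDB archive into this
directory to enable the check. All other tests are self-contained.
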