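# Default pKa table for sequence-derived ionizable groups.
#
# valence: formal valence of the *charged* state (+1 basic, -1 acidic)
# ion_radius: radius (nm) of the ionized group used in the Born solvation term
# source: "measured-nominal" entries are the load-bearing nominal values used
#         throughout the model; "conventional" entries are standard textbook
#         defaults and can be overridden per run.
protein:
  ASP: {pka: 4.0, valence: -1, ion_radius: 0.25, source: conventional}
  GLU: {pka: 4.3, valence: -1, ion_radius: 0.25, source: measured-nominal}
  LYS: {pka: 10.4, valence: 1, ion_radius: 0.25, source: measured-nominal}
  CYS: {pka: 8.2, valence: -1, ion_radius: 0.25, source: measured-nominal}
  HIS: {pka: 6.0, valence: 1, ion_radius: 0.25, source: conventional}
  ARG: {pka: 12.0, valence: 1, ion_radius: 0.25, source: conventional}
  TYR: {pka: 10.0, valence: -1, ion_radius: 0.25, source: conventional}
  NTERM: {pka: 8.0, valence: 1, ion_radius: 0.25, source: conventional}
  CTERM: {pka: 3.6, valence: -1, ion_radius: 0.25, source: conventional}
nucleic:
  PHOSPHATE: {pka: 2.0, valence: -1, ion_radius: 0.25, source: conventional}
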