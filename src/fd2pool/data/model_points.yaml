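# Operating points of the release-mode phase plane: pairs of site occupancy
# (p_occ) and baseline facilitation probability (f_base) for one active zone
# with seven docking sites, probed with a 50 ms paired-pulse protocol.
#
#   a: high occupancy, high success  -> multivesicular, strong depression
#   b: low occupancy, high success   -> univesicular, same depression as a
#   c: low occupancy, low success    -> univesicular, facilitating
#   d: high occupancy, low success   -> multivesicular, same facilitation as c
n_t: 7
isi_ms: 50.0
points:
  a: {p_occ: 0.7142857142857143, f_base: 0.90}
  b: {p_occ: 0.14285714285714285, f_base: 0.90}
  c: {p_occ: 0.30, f_base: 0.40}
  d: {p_occ: 0.786, f_base: 0.40}
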