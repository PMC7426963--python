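# Batch configuration for the eight published free/bound Fab couples.
#
# Entries are fetched from the RCSB by accession (network required) and
# cached.  IMPORTANT: heavy/light chain ids vary between PDB entries and
# must be checked against the downloaded files before a production run
# (`fabcompare fetch <codes>` then inspect, or read the entry header);
# the H/L defaults below are placeholders for entries that use the
# conventional Fab chain naming.  For multi-copy asymmetric units (e.g.
# the twelve Fab copies of 2FJF) pick one copy with `fab_copy` windows
# and/or the chain ids of that copy; the report logs the selection.
# Anchor overrides follow the same per-couple pattern when the default
# conserved-anchor selection does not match the entry.

max_resolution: 3.0
cache_dir: pdb_cache
couples:
  - couple_id: 3G6A/3G6D
    free: 3G6A
    bound: 3G6D
    heavy_chain_id: H
    light_chain_id: L
    light_chain_type: light_kappa
  - couple_id: 3HMW/3HMX
    free: 3HMW
    bound: 3HMX
    heavy_chain_id: H
    light_chain_id: L
    light_chain_type: light_kappa
  - couple_id: 3EO9/3EOA
    free: 3EO9
    bound: 3EOA
    heavy_chain_id: H
    light_chain_id: L
    light_chain_type: light_kappa
  - couple_id: 3EO9/3EOB
    free: 3EO9
    bound: 3EOB
    heavy_chain_id: H
    light_chain_id: L
    light_chain_type: light_kappa
  - couple_id: 1MLB/1MLC
    free: 1MLB
    bound: 1MLC
    heavy_chain_id: B
    light_chain_id: A
    light_chain_type: light_kappa
  - couple_id: 1DQQ/1DQJ
    free: 1DQQ
    bound: 1DQJ
    heavy_chain_id: B
    light_chain_id: A
    light_chain_type: light_kappa
  - couple_id: 5BVJ/5BVP
    free: 5BVJ
    bound: 5BVP
    heavy_chain_id: H
    light_chain_id: L
    light_chain_type: light_kappa
  - couple_id: 2FJF/2FJG
    free: 2FJF
    bound: 2FJG
    heavy_chain_id: H
    light_chain_id: L
    light_chain_type: light_kappa
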