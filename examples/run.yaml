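# One run of the static-partitioning cascade near criticality.
lattice:
  L: 64
thermo:
  tau: 1.05
  m_target: 0.0
  J: 1.0
  J_int: 1.0
network: fig1        # bundled; or a path to your own network YAML
run:
  sweeps: 50000
  record_every: 100
  snapshots_every: 10000
  seed: 7
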