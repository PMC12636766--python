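# Partition-switching cascade (palmitoylation-like): activation flips the
# target's domain preference from disordered to ordered, so reactions feed
# back on the configurational ensemble and detailed balance is broken.
# Both activator and inactivator prefer the ordered phase.
target: T
target_active_state: active
components:
  - name: A          # activator / "recruiter"
    radius: 0
    count: 10
    mobility: 0.1
    states: [active]
    boundary_pref: {active: 1}
  - name: I          # inactivator / "excluder"
    radius: 0
    count: 10
    mobility: 0.1
    states: [active]
    boundary_pref: {active: 1}
  - name: T          # target: disordered when inactive, ordered when active
    radius: 0
    count: 20
    mobility: 0.1
    states: [inactive, active]
    boundary_pref: {inactive: -1, active: 1}
rules:
  - actor: [A, active]
    substrate: [T, inactive]
    product_state: active
    rate: 1.0
    activity_sign: 1
  - actor: [I, active]
    substrate: [T, active]
    product_state: inactive
    rate: 1.0
    activity_sign: -1
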