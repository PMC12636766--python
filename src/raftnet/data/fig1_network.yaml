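# Static-partitioning cascade: an activator (disordered-preferring) turns
# the target on by contact; an inactivator (ordered-preferring, like the
# target) turns it off.  Both pathway sign products are positive, so target
# activity is predicted to rise with the rescaled temperature.
target: T
target_active_state: active
components:
  - name: A          # activator, e.g. a kinase excluded from rafts
    radius: 0
    count: 10
    mobility: 0.1
    states: [active]
    boundary_pref: {active: -1}
  - name: I          # inactivator, e.g. a raft-partitioning phosphatase
    radius: 0
    count: 10
    mobility: 0.1
    states: [active]
    boundary_pref: {active: 1}
  - name: T          # tracked target receptor
    radius: 0
    count: 20
    mobility: 0.1
    states: [inactive, active]
    boundary_pref: {inactive: 1, active: 1}
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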