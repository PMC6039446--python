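{
  "name": "five_state_roux",
  "states": ["1", "2", "3", "4", "5"],
  "occupancy": {
    "1": "S1,S3 occupied (two ions deep in the filter)",
    "2": "S1,S3 occupied + ion in the cavity at the inner mouth",
    "3": "S0,S2,S4 occupied (three ions in the filter, outermost site S0 filled)",
    "4": "S2,S4 occupied + ion in the outer pore mouth just outside S0",
    "5": "S2,S4 occupied (two ions in the filter)"
  },
  "edges": [
    {"from": "1", "to": "2", "param": "k12", "kind": "bind_internal"},
    {"from": "2", "to": "1", "param": "k21", "kind": "plain"},
    {"from": "2", "to": "3", "param": "k23", "kind": "eyring", "eyring_group": "23"},
    {"from": "3", "to": "2", "param": "k32", "kind": "eyring", "eyring_group": "23"},
    {"from": "3", "to": "4", "param": "k34", "kind": "plain"},
    {"from": "4", "to": "3", "param": "k43", "kind": "plain"},
    {"from": "4", "to": "5", "param": "k45", "kind": "plain"},
    {"from": "5", "to": "4", "param": "k54", "kind": "bind_external"},
    {"from": "5", "to": "1", "param": "k51", "kind": "eyring", "eyring_group": "51"},
    {"from": "1", "to": "5", "param": "k15", "kind": "eyring", "eyring_group": "51"}
  ],
  "transport_cycle": ["1", "2", "3", "4", "5", "1"],
  "constraint_eliminated_rate": "k21",
  "notes": "Five-state ion-hopping cycle: internal binding (1->2), concerted voltage-dependent translocation (2->3), release of the S0 ion to the outer mouth (3->4), unbinding to the external solution (4->5), and a second voltage-dependent translocation resetting the filter (5->1). Forward traversal of the cycle moves one charge outward."
}
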