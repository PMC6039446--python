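{
  "name": "four_state",
  "states": ["1", "2", "3", "5"],
  "occupancy": {
    "1": "S1,S3 occupied (two ions deep in the filter)",
    "2": "S1,S3 occupied + ion in the cavity at the inner mouth",
    "3": "S0,S2,S4 occupied (three ions in the filter, outermost site S0 filled)",
    "5": "S2,S4 occupied (two ions in the filter)"
  },
  "edges": [
    {"from": "1", "to": "2", "param": "k12", "kind": "bind_internal"},
    {"from": "2", "to": "1", "param": "k21", "kind": "plain"},
    {"from": "2", "to": "3", "param": "k23", "kind": "eyring", "eyring_group": "23"},
    {"from": "3", "to": "2", "param": "k32", "kind": "eyring", "eyring_group": "23"},
    {"from": "3", "to": "5", "param": "k35", "kind": "plain"},
    {"from": "5", "to": "3", "param": "k53", "kind": "bind_external"},
    {"from": "5", "to": "1", "param": "k51", "kind": "eyring", "eyring_group": "51"},
    {"from": "1", "to": "5", "param": "k15", "kind": "eyring", "eyring_group": "51"}
  ],
  "transport_cycle": ["1", "2", "3", "5", "1"],
  "constraint_eliminated_rate": "k21",
  "notes": "Four-state variant obtained by removing the outer-mouth binding site (state 4) from the five-state cycle: the S0 ion is released directly to the external solution (3->5 plain, re-binding 5->3 proportional to external activity)."
}
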