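{
  "name": "hard_knock_on",
  "states": ["1", "2", "3", "4", "5"],
  "occupancy": {
    "1": "S1,S2,S3 occupied (three ions in direct contact)",
    "2": "S1,S2,S3 occupied + ion at the inner entry",
    "3": "S0,S1,S2 occupied + entering ion at S4 (stack shifted outward by direct knock-on)",
    "4": "S1,S2,S4 occupied + outermost ion expelled to the outer mouth",
    "5": "S1,S2,S4 occupied after release of the outer-mouth ion"
  },
  "edges": [
    {"from": "1", "to": "2", "param": "k12", "kind": "bind_internal"},
    {"from": "2", "to": "1", "param": "k21", "kind": "plain"},
    {"from": "2", "to": "3", "param": "k23", "kind": "eyring", "eyring_group": "A"},
    {"from": "3", "to": "2", "param": "k32", "kind": "eyring", "eyring_group": "A"},
    {"from": "3", "to": "4", "param": "k34", "kind": "eyring", "eyring_group": "B"},
    {"from": "4", "to": "3", "param": "k43", "kind": "eyring", "eyring_group": "B"},
    {"from": "4", "to": "5", "param": "k45", "kind": "plain"},
    {"from": "5", "to": "4", "param": "k54", "kind": "bind_external"},
    {"from": "5", "to": "1", "param": "k51", "kind": "plain"},
    {"from": "1", "to": "5", "param": "k15", "kind": "plain"}
  ],
  "transport_cycle": ["1", "2", "3", "4", "5", "1"],
  "constraint_eliminated_rate": "k21",
  "notes": "APPROXIMATE direct ('hard') knock-on cycle: ions in direct contact move concertedly, with voltage placed on the two concerted translocation steps (groups A and B) and serial steps sharing no independent condition dependence merged. The edge-by-edge assignment is a best-effort reading of the published scheme and is configurable via this JSON document rather than hard-coded."
}
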