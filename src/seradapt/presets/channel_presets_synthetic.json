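{
  "_comment": "SYNTHETIC PLACEHOLDER channel constants per cortical area. kappa_phi is the tuning concentration at maximum contrast in double-angle units; c50/c_exp are the Naka-Rushton contrast-response constants. These are order-of-magnitude stand-ins for published primate electrophysiology medians, not transcribed measurements; replace with values from a meta-analysis before interpreting preset comparisons physiologically. No test or result in this package depends on these numbers.",
  "V1": {"kappa_phi": 3.0, "c50": 0.33, "c_exp": 2.4},
  "V2": {"kappa_phi": 2.2, "c50": 0.26, "c_exp": 2.5},
  "V5": {"kappa_phi": 1.2, "c50": 0.082, "c_exp": 2.35}
}
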