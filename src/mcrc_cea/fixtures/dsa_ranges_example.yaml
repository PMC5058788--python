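# Example one-way sensitivity range file for `mcrc-cea dsa --ranges ...`
# Paths are dot-addressed into the analysis config (strategies by name).
outcome:
  kind: icer
  intervention: RAS-Cetux
  comparator: RAS-Bev
ranges:
  - {path: "strategies.RAS-Cetux.utilities.stable", low: 0.85, high: 0.89, base: 0.85}
  - {path: "strategies.RAS-Bev.transition_overrides.p_pd_to_dead", low: 0.0278, high: 0.0417, base: 0.0342}
  - {path: "strategies.RAS-Cetux.costs.progression_cost_per_month", low: 5760.0, high: 8640.0, base: 7200.0}
  - {path: "settings.discount.annual_rate", low: 0.0, high: 0.05, base: 0.03}
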