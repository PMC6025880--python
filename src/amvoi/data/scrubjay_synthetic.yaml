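# SYNTHETIC stand-in for the Florida scrub-jay habitat management problem.
# These numbers are constructed to mirror the qualitative structure of the
# published analysis (whose transition probabilities and returns live in a
# supplementary file that is not redistributed here); they are NOT the
# published estimates and results computed from them are illustrative only.
#
# Structure emulated:
#   - succession advances under do-nothing (short -> optimal -> tall-mix,
#     open -> closed);
#   - burns set vegetation back toward short-open; open classes respond
#     well, closed and tall-mix classes resist;
#   - the null model's routine and intensive burns are identical, so the
#     dearer intensive burn is never optimal when the null model is certain;
#   - the alternative model's intensive burn is markedly more effective in
#     the fire-resistant classes (short-closed, optimal-closed, tall-mix),
#     where the optimal policy uses it unless the null model is (near)
#     certain — and only there;
#   - returns reflect scrub-jay demographic performance by habitat class
#     (optimal-open the source habitat, closed and tall classes sinks) net
#     of burn cost.
name: scrubjay-synthetic
states: [short-open, short-closed, optimal-open, optimal-closed, tall-mix]
actions: [do-nothing, routine-burn, intensive-burn]
models: ["null", alternative]
discount: 1.0
horizon: 2000
rewards:
  do-nothing: [0.2, 0.0, 1.0, 0.25, 0.0]
  routine-burn: [0.1, -0.1, 0.9, 0.15, -0.1]
  intensive-burn: [-0.05, -0.25, 0.75, 0.0, -0.25]
transitions:
  "null":
    do-nothing:
      - [0.40, 0.40, 0.15, 0.05, 0.00]
      - [0.00, 0.60, 0.02, 0.23, 0.15]
      - [0.05, 0.00, 0.55, 0.30, 0.10]
      - [0.00, 0.02, 0.03, 0.60, 0.35]
      - [0.00, 0.00, 0.00, 0.05, 0.95]
    routine-burn:
      - [0.70, 0.20, 0.10, 0.00, 0.00]
      - [0.15, 0.70, 0.02, 0.13, 0.00]
      - [0.30, 0.05, 0.55, 0.10, 0.00]
      - [0.08, 0.12, 0.05, 0.55, 0.20]
      - [0.05, 0.10, 0.03, 0.12, 0.70]
    intensive-burn:
      - [0.70, 0.20, 0.10, 0.00, 0.00]
      - [0.15, 0.70, 0.02, 0.13, 0.00]
      - [0.30, 0.05, 0.55, 0.10, 0.00]
      - [0.08, 0.12, 0.05, 0.55, 0.20]
      - [0.05, 0.10, 0.03, 0.12, 0.70]
  alternative:
    do-nothing:
      - [0.40, 0.40, 0.15, 0.05, 0.00]
      - [0.00, 0.60, 0.02, 0.23, 0.15]
      - [0.05, 0.00, 0.55, 0.30, 0.10]
      - [0.00, 0.02, 0.03, 0.60, 0.35]
      - [0.00, 0.00, 0.00, 0.05, 0.95]
    routine-burn:
      - [0.70, 0.20, 0.10, 0.00, 0.00]
      - [0.15, 0.70, 0.02, 0.13, 0.00]
      - [0.30, 0.05, 0.55, 0.10, 0.00]
      - [0.08, 0.12, 0.05, 0.55, 0.20]
      - [0.05, 0.10, 0.03, 0.12, 0.70]
    intensive-burn:
      - [0.75, 0.15, 0.10, 0.00, 0.00]
      - [0.65, 0.25, 0.03, 0.07, 0.00]
      - [0.32, 0.05, 0.55, 0.08, 0.00]
      - [0.45, 0.15, 0.10, 0.25, 0.05]
      - [0.40, 0.20, 0.08, 0.12, 0.20]
# External signal: the observed one-year response of a short-closed unit at
# another site to an intensive burn. Outcome laws are the corresponding
# transition rows, which overlap between models, so a single observation
# discriminates only weakly.
signal:
  outcomes: [short-open, short-closed, optimal-open, optimal-closed, tall-mix]
  distributions:
    "null": [0.15, 0.70, 0.02, 0.13, 0.00]
    alternative: [0.65, 0.25, 0.03, 0.07, 0.00]
monitoring_period: 2
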