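# Condition bands classifying a symptom value as pathological-high (a),
# pathological-low (b) or normal (c).  Bounds may be arithmetic expressions
# over Wt (weight, kg), L (height, cm) and Q = 0.0061*L + 0.0128*Wt - 0.1592.
# "approx" bands are closed intervals value*(1 +/- approx_tol).
approx_tol: 0.10
bands:
  - {symptom: SP,  label: a, op: ge, value: 160}
  - {symptom: SP,  label: b, op: lt, value: 90}
  - {symptom: SP,  label: c, op: range, lo: 110, hi: 130}
  - {symptom: DP,  label: a, op: ge, value: 95}
  - {symptom: DP,  label: c, op: range, lo: 80, hi: 90}
  - {symptom: MAP, label: a, op: gt, value: 115}
  - {symptom: MAP, label: b, op: lt, value: 65}
  - {symptom: MAP, label: c, op: range, lo: 70, hi: 100}
  - {symptom: MDP, label: a, op: gt, value: 105}
  - {symptom: MDP, label: c, op: range, lo: 66, hi: 96}
  - {symptom: BV,  label: a, op: le, value: "0.75 * Wt * 0.075"}
  - {symptom: BV,  label: c, op: range, lo: "0.75 * Wt * 0.075", hi: "1.25 * Wt * 0.075"}
  - {symptom: PR,  label: a, op: ge, value: 104}
  - {symptom: PR,  label: b, op: lt, value: 50}
  - {symptom: PR,  label: c, op: range, lo: 60, hi: 100}
  - {symptom: Wt,  label: a, op: gt, value: 20}
  - {symptom: Wt,  label: c, op: range, lo: 50, hi: 80}
  - {symptom: SV,  label: a, op: le, value: "0.8 * (1 + Q) * 20 * Q"}
  - {symptom: SV,  label: b, op: ge, value: "1.3 * 1.2 * (1 + Q) * 20 * Q"}
  - {symptom: SV,  label: c, op: approx, value: "(1 + Q) * 20 * Q"}
  - {symptom: SI,  label: a, op: le, value: "0.8 * (1 + Q) * 20"}
  - {symptom: SI,  label: b, op: ge, value: "1.3 * 1.2 * (1 + Q) * 20"}
  - {symptom: SI,  label: c, op: approx, value: "(1 + Q) * 20"}
  - {symptom: VPE, label: a, op: le, value: "0.8 * 2 * (Wt + 45) * 0.0112"}
  - {symptom: VPE, label: b, op: ge, value: "1.2 * 2 * (Wt + 45) * 0.0112"}
  - {symptom: VPE, label: c, op: approx, value: "(2 * Wt + 45) * 0.0112"}
  - {symptom: CI,  label: a, op: ge, value: 2.2}
  - {symptom: CI,  label: c, op: range, lo: "(1 + Q) * 1.2", hi: "(1 + Q) * 2"}
  - {symptom: Y,   label: a, op: ge, value: "1.1 * 4"}
  - {symptom: Y,   label: b, op: le, value: "0.85 * 3"}
  - {symptom: Y,   label: c, op: range, lo: 3, hi: 4}
  - {symptom: Yr,  label: a, op: ge, value: "1.1 * 4"}
  - {symptom: Yr,  label: b, op: le, value: "0.85 * 3"}
  - {symptom: Yr,  label: c, op: range, lo: 3, hi: 4}
  # The source table prints ">=1.2" for both a and c on the AC row (an
  # apparent duplication); only a is kept, c is absent.
  - {symptom: AC,  label: a, op: ge, value: 1.2}
  - {symptom: FEK, label: a, op: ge, value: "0.9 * 0.25"}
  - {symptom: FEK, label: c, op: range, lo: 0.35, hi: 0.55}
  - {symptom: BLK, label: a, op: lt, value: "0.85 * 0.22"}
  - {symptom: BLK, label: c, op: range, lo: 0.22, hi: 0.26}
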