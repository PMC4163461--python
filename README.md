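# hbfin

Hierarchical Bayesian fuzzy inference nets for cardiovascular diagnosis
from pulse-wave hemodynamic parameters.

`hbfin` is a clinical-decision-support toolkit for researchers working
with sphygmogram (SPG, arterial pulse waveform) data.  It covers the full
pipeline from waveform morphology to a ranked, explainable diagnosis:

1. **Hemodynamics** — derive hemodynamic parameters (HDPs) from SPG
   morphological features via the elastic-cavity solution:
   k = (P̄ − P_d)/(P_s − P_d), SV = 0.28·k²·T·(P_s − P_d), η = 1 + A_s/A_d,
   AC = SV/(η·(P_s − P_d)), R = (P̄ − P_v)/(SV·T).
2. **Condition bands** — classify each symptom value into a pathological
   (`a`, `b`) or normal (`c`) band; bounds may depend on the patient's
   weight, height and body-size factor Q = 0.0061·L + 0.0128·Wt − 0.1592.
3. **Knowledge base → net** — parse universally quantified function
   formulas such as `forall p. SPa(p) & MDPa(p) & MAPa(p) & DPa(p) -> HT(p)`
   and mechanically assemble a staged, acyclic inference net in which
   intermediate hypotheses (e.g. low blood volume) feed later stages
   (e.g. hypotension).
4. **Fuzzy quantification** — fit membership functions (high-order
   polynomial, S-type logistic, or quasi-Gaussian) from labeled cohorts
   by histogram frequency analysis; a symptom's membership grade f sets
   its node's parameters dynamically: probability = f and LS = α·f when
   f ≥ 0.2 (α = 100), or LN = β·f when f < 0.2 (β = 10).  Hypothesis
   nodes are quantified by the principle of indifference
   (prior 0.02, LS 200, LN 0.01).
5. **Inference** — odds-likelihood Bayesian updating, O(h|x) = [∏L_i]·O(h)
   with O(h) = P(h)/(1 − P(h)), propagated stage by stage; conjunction
   and disjunction nodes collapse evidence by min/max, and uncertain
   evidence interpolates piecewise-linearly between the certain-false,
   prior, and certain-true posteriors.  Every posterior carries a full
   evidence trace back to the raw symptom values.
6. **Synthetic cohorts** — generate labeled patient cohorts whose symptom
   values respect the condition bands per diagnosis class, for testing
   and benchmarking without any clinical data.

## Worked example

The package ships a partial medical record of a hypertensive patient
(16 symptom values: SP 168 mmHg, DP 100 mmHg, MAP 130.98 mmHg, ...).
Diagnosing it against the bundled knowledge base with crisp condition-band
grading:

```python
from hbfin import bundled_net, diagnose, explain, table2_fixture

result = diagnose(bundled_net(), table2_fixture())
print({h: round(result.posteriors[h], 6) for h in result.ranking[:3]})
print(explain(result, "HT"))
```

prints

```
{'HT': 0.803213, 'High_BE': 0.02, 'Low_BE': 0.02}
HT (stage 2): prior 0.02 -> posterior 0.803213
  rule: evidence certain: odds x LS
  LS=200 LN=0.01 P(x|e)=1
  <- DPa: grade 1 (certain_true, LS=100)
  <- MAPa: grade 1 (certain_true, LS=100)
  <- MDPa: grade 1 (certain_true, LS=100)
  <- SPa: grade 1 (certain_true, LS=100)
```

All four pressure symptoms fall in their hypertensive bands, so the
conjunction is certainly true and the hypertension (HT) posterior rises
from the indifference prior 0.02 to 200·(0.02/0.98)/(1 + 200·(0.02/0.98))
≈ 0.8032.  Every other hypothesis stays at its prior (its evidence is
unknown for this partial record) or is driven toward zero by
certainly-false evidence.  The same run from the shell:

```bash
hbfin diagnose --record patient.csv --crisp --explain HT
```

The full pipeline on synthetic data:

```bash
hbfin simulate --out cohort.csv --seed 2 --n-per-class 50
hbfin evaluate --cohort cohort.csv --seed 2      # fit MFs on 75%, test on 25%
```

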