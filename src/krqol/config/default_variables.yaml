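# Default dichotomization recipe for the knee-replacement QOL analysis.
# labels: [high-state label, low-state label]; fixed cut-offs are
# inclusive on the high side (value >= cutoff -> high state).
# for categorical variables the labels follow the declared level order
sex:
  method: categorical_passthrough
  labels: [Female sex, Male sex]
joint_type:
  method: categorical_passthrough
  labels: ["Artificial joint type: unilateral", "Artificial joint type: bilateral"]
age:
  method: fixed_cutoff
  cutoff: 60
  labels: [Old age, Young age]
bmi:
  method: fixed_cutoff
  cutoff: 30
  labels: [Obesity, Non-obesity]
sit_to_stand_s:
  method: median_split
  labels: [Decreased ability to stand, Preserved ability to stand]
cci:
  method: fixed_cutoff
  cutoff: 1
  labels: [Comorbidities, No comorbidities]
cesd:
  method: fixed_cutoff
  cutoff: 16
  labels: [Depressive symptoms, Non-depressive symptoms]
womac_pain:
  method: median_split
  labels: [High preoperative WOMAC-pain score, Low preoperative WOMAC-pain score]
womac_stiffness:
  method: median_split
  labels: [High preoperative WOMAC-stiffness score, Low preoperative WOMAC-stiffness score]
womac_physfunc:
  method: median_split
  labels: [High preoperative WOMAC-physical function score, Low preoperative WOMAC-physical function score]
pcs_pre:
  method: fixed_cutoff
  cutoff: 50
  labels: [High preoperative PCS, Low preoperative PCS]
pcs_1y:
  method: fixed_cutoff
  cutoff: 50
  labels: [High PCS at 1 year postoperatively, Low PCS at 1 year postoperatively]
pcs_2y:
  method: fixed_cutoff
  cutoff: 50
  labels: [High PCS at 2 years postoperatively, Low PCS at 2 years postoperatively]
mcs_pre:
  method: fixed_cutoff
  cutoff: 50
  labels: [High preoperative MCS, Low preoperative MCS]
mcs_1y:
  method: fixed_cutoff
  cutoff: 50
  labels: [High MCS at 1 year postoperatively, Low MCS at 1 year postoperatively]
mcs_2y:
  method: fixed_cutoff
  cutoff: 50
  labels: [High MCS at 2 years postoperatively, Low MCS at 2 years postoperatively]
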