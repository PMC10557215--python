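schema_id: slr2
entities:
  - name: age_metric
    description: Metric used to measure the age of patient populations
  - name: age_number
    description: Numeric measurement associated with an age metric
  - name: arm_description
    description: Treatment arm description phrase
  - name: arm_dosage
    description: Amount or frequency of a treatment
  - name: egfr_metric
    description: Metric used to describe eGFR
  - name: egfr_number
    description: Numeric measurement associated with an eGFR metric
  - name: egfr_subgroup
    description: Population subgroup
  - name: egfr_time_point
    description: Time period over which the metric was measured
  - name: study_type
    description: Type of study design
relations:
  - label: refers_to
    first: arm_description
    second: arm_dosage
  - label: refers_to
    first: egfr_metric
    second: age_number
  - label: refers_to
    first: egfr_metric
    second: egfr_number
  - label: refers_to
    first: egfr_metric
    second: egfr_subgroup
  - label: refers_to
    first: egfr_metric
    second: egfr_time_point
  - label: refers_to
    first: egfr_number
    second: egfr_subgroup
  - label: refers_to
    first: age_metric
    second: age_number
  - label: equivalent
    first: ANY
    second: ANY
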