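schema_id: slr1
entities:
  - name: arm_description
    description: Treatment arm description phrase
  - name: arm_dosage
    description: Amount or frequency of a treatment
  - name: pfs_metric
    description: Metric used to describe progression-free survival
  - name: pfs_result
    description: Numeric measurement associated with a PFS metric
  - name: study_type
    description: Type of study design
  - name: title
    description: Title of the publication
  - name: authors
    description: Authors of the publication
relations:
  - label: refers_to
    first: arm_description
    second: arm_dosage
  - label: refers_to
    first: arm_description
    second: pfs_metric
  - label: refers_to
    first: pfs_metric
    second: pfs_result
  - label: equivalent
    first: ANY
    second: ANY
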