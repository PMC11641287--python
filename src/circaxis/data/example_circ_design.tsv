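sample_id	group	pair_id
BC_tumor_1	tumor	patient_56y
BC_tumor_2	tumor	patient_38y
BC_tumor_3	tumor	patient_67y
BC_tumor_4	tumor	patient_47y
BC_tumor_5	tumor	patient_54y
BC_normal_1	normal	patient_56y
BC_normal_2	normal	patient_38y
BC_normal_3	normal	patient_67y
BC_normal_4	normal	patient_47y
BC_normal_5	normal	patient_54y
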