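category,item,MELD,MESO-Index,UKELD,iMELD,refitMELD,refitMELDNa,upMELD,MELDNa,PELD
internal_validity,inception_cohort_established,0.67,1,1,1,1,1,1,1,1
internal_validity,inception_cohort_followed_up,1,1,1,1,0.67,0.67,1,1,1
internal_validity,baseline_data_prospective,1,0.33,0.67,0.33,0.67,0.67,0.67,0.67,0.67
internal_validity,candidate_factors_defined,0.67,0.67,0.67,0.67,0.67,0.67,0.67,0.67,1
external_validity,multicentre_population,2,0,2,2,2,2,2,2,2
external_validity,adequate_description,1.34,0.67,2,1.34,1.34,1.34,1.34,1.34,1.34
statistical_validity,continuous_variables,0.67,0.67,0.67,0.67,1,1,0.67,0.67,1
statistical_validity,sample_size_adequate,1,0.67,1,0.67,1,1,1,1,1
statistical_validity,collinearity_assessed,0,0,0.33,0,0.33,0.33,0.33,0,0
statistical_validity,missing_values,0.33,0,0,0,0,0,0,0,0.67
evaluation_of_model,model_assumptions_tested,0.67,1,1,1,1,1,1,0.67,0.67
evaluation_of_model,sensitivity_influential_observations,0.67,1,0.33,1,0,0,0.33,0.33,1
evaluation_of_model,internal_validation,0.33,1,0.33,1,0,0,0.33,0.33,1
evaluation_of_model,external_validation,0.33,0.33,1,0.67,1,1,1,1,0.67
practicality,factors_available_in_practice,1,1,1,1,1,1,1,1,1
practicality,model_described_sufficiently,1,1,1,0.67,1,1,1,1,0.67
practicality,prediction_precision,0.67,1,1,1,1,1,0.67,0.67,0.67
practicality,wide_generalisability,1,0.67,1,1,1,1,1,1,0.67
,printed_total,14.32,11,16,14.02,15.01,15.01,15.01,14.35,15.36
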