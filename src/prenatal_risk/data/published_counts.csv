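variable,category,n_total,n_events
marital_status,married,423,2
marital_status,unmarried,27,2
marital_status,not_answered,26,1
marital_status,not_investigated,417,6
maternal_age,25-39,753,6
maternal_age,<20,13,1
maternal_age,20-24,94,3
maternal_age,>=40,33,1
late_registration,no,812,9
late_registration,yes,55,2
late_registration,not_answered,26,0
pregnancy_progress,good/not_answered,557,8
pregnancy_progress,not_good,10,0
pregnancy_progress,not_investigated,326,3
birth_order,subsequent/not_answered,495,7
birth_order,first,398,4
abortion_history,no/not_answered,834,7
abortion_history,yes,59,4
infertility_treatment,no,696,10
infertility_treatment,yes,67,0
infertility_treatment,not_answered,6,0
infertility_treatment,not_investigated,124,1
feeling_at_pregnancy,happy,647,7
feeling_at_pregnancy,unexpected_happy,185,2
feeling_at_pregnancy,unexpected_other,54,1
feeling_at_pregnancy,not_answered,7,1
return_to_parents_home,yes,317,2
return_to_parents_home,no,440,8
return_to_parents_home,not_answered,12,0
return_to_parents_home,not_investigated,124,1
has_helper,yes,870,9
has_helper,no,13,1
has_helper,not_answered,10,1
worries_anxiety,no,418,4
worries_anxiety,yes,264,5
worries_anxiety,not_answered,9,0
worries_anxiety,not_investigated,202,2
smoking,no/not_answered,776,6
smoking,stopped,94,3
smoking,yes,23,2
passive_smoking,no/not_answered,481,5
passive_smoking,yes,86,3
passive_smoking,not_investigated,326,3
alcohol,no,874,10
alcohol,yes,8,1
alcohol,not_answered,11,0
disease_history,no/not_answered,476,6
disease_history,yes,91,2
disease_history,not_investigated,326,3
mental_illness_history,no,310,3
mental_illness_history,yes,25,1
mental_illness_history,not_answered,434,6
mental_illness_history,not_investigated,124,1
depressive_symptoms,no,820,9
depressive_symptoms,yes,66,2
depressive_symptoms,not_answered,7,0
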