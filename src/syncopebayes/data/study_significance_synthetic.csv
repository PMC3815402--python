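predictor,study_id
age_category,alboni
age_category,calkins
age_category,iglesias
age_category,sud
gender,alboni
gender,calkins
gender,delrosso_b
gender,galizia
gender,iglesias
gender,sud
structural_heart_disease,delrosso_a
structural_heart_disease,sud
structural_heart_disease,galizia
number_of_spells,calkins
number_of_spells,delrosso_a
number_of_spells,alboni
nausea,alboni
nausea,calkins
nausea,delrosso_a
nausea,galizia
nausea,iglesias
diaphoresis,alboni
diaphoresis,calkins
diaphoresis,delrosso_a
diaphoresis,delrosso_b
diaphoresis,galizia
diaphoresis,iglesias
prodrome,alboni
prodrome,calkins
prodrome,delrosso_a
prodrome,delrosso_b
prodrome,galizia
prodrome,iglesias
blurred_vision,alboni
blurred_vision,calkins
blurred_vision,delrosso_a
blurred_vision,delrosso_b
blurred_vision,galizia
blurred_vision,iglesias
palpitations,alboni
palpitations,calkins
palpitations,delrosso_b
palpitations,iglesias
supine_syncope,alboni
supine_syncope,calkins
supine_syncope,delrosso_b
effort_syncope,alboni
effort_syncope,delrosso_b
effort_syncope,delrosso_a
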