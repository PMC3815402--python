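study_id,predictor,class,level,count
table_totals,age_category,cardiac,<40,3
table_totals,age_category,cardiac,40-60,65
table_totals,age_category,cardiac,>=60,226
table_totals,age_category,noncardiac,<40,234
table_totals,age_category,noncardiac,40-60,427
table_totals,age_category,noncardiac,>=60,363
alboni,gender,cardiac,male,49
alboni,gender,cardiac,female,29
alboni,gender,noncardiac,male,133
alboni,gender,noncardiac,female,126
calkins,gender,cardiac,male,41
calkins,gender,cardiac,female,7
calkins,gender,noncardiac,male,10
calkins,gender,noncardiac,female,22
delrosso_b,gender,cardiac,male,34
delrosso_b,gender,cardiac,female,10
delrosso_b,gender,noncardiac,male,122
delrosso_b,gender,noncardiac,female,94
galizia,gender,cardiac,male,12
galizia,gender,cardiac,female,22
galizia,gender,noncardiac,male,74
galizia,gender,noncardiac,female,100
iglesias,gender,cardiac,male,90
iglesias,gender,cardiac,female,58
iglesias,gender,noncardiac,male,388
iglesias,gender,noncardiac,female,403
sud,gender,cardiac,male,12
sud,gender,cardiac,female,8
sud,gender,noncardiac,male,16
sud,gender,noncardiac,female,16
delrosso_a,structural_heart_disease,cardiac,yes,107
delrosso_a,structural_heart_disease,cardiac,no,9
delrosso_a,structural_heart_disease,noncardiac,yes,77
delrosso_a,structural_heart_disease,noncardiac,no,219
sud,structural_heart_disease,cardiac,yes,11
sud,structural_heart_disease,cardiac,no,9
sud,structural_heart_disease,noncardiac,yes,8
sud,structural_heart_disease,noncardiac,no,24
calkins,number_of_spells,cardiac,<=2,37
calkins,number_of_spells,cardiac,>2,11
calkins,number_of_spells,noncardiac,<=2,4
calkins,number_of_spells,noncardiac,>2,28
delrosso_a,number_of_spells,cardiac,<=2,77
delrosso_a,number_of_spells,cardiac,>2,39
delrosso_a,number_of_spells,noncardiac,<=2,120
delrosso_a,number_of_spells,noncardiac,>2,176
alboni,nausea,cardiac,yes,4
alboni,nausea,cardiac,no,74
alboni,nausea,noncardiac,yes,34
alboni,nausea,noncardiac,no,225
calkins,nausea,cardiac,yes,2
calkins,nausea,cardiac,no,46
calkins,nausea,noncardiac,yes,16
calkins,nausea,noncardiac,no,16
delrosso_a,nausea,cardiac,yes,7
delrosso_a,nausea,cardiac,no,109
delrosso_a,nausea,noncardiac,yes,45
delrosso_a,nausea,noncardiac,no,251
galizia,nausea,cardiac,yes,2
galizia,nausea,cardiac,no,32
galizia,nausea,noncardiac,yes,38
galizia,nausea,noncardiac,no,136
iglesias,nausea,cardiac,yes,19
iglesias,nausea,cardiac,no,129
iglesias,nausea,noncardiac,yes,174
iglesias,nausea,noncardiac,no,617
table_totals,diaphoresis,cardiac,yes,86
table_totals,diaphoresis,cardiac,no,382
table_totals,diaphoresis,noncardiac,yes,753
table_totals,diaphoresis,noncardiac,no,1015
alboni,prodrome,cardiac,yes,46
alboni,prodrome,cardiac,no,32
alboni,prodrome,noncardiac,yes,172
alboni,prodrome,noncardiac,no,87
calkins,prodrome,cardiac,yes,9
calkins,prodrome,cardiac,no,39
calkins,prodrome,noncardiac,yes,21
calkins,prodrome,noncardiac,no,11
delrosso_a,prodrome,cardiac,yes,23
delrosso_a,prodrome,cardiac,no,93
delrosso_a,prodrome,noncardiac,yes,96
delrosso_a,prodrome,noncardiac,no,200
delrosso_b,prodrome,cardiac,yes,21
delrosso_b,prodrome,cardiac,no,23
delrosso_b,prodrome,noncardiac,yes,160
delrosso_b,prodrome,noncardiac,no,56
galizia,prodrome,cardiac,yes,4
galizia,prodrome,cardiac,no,30
galizia,prodrome,noncardiac,yes,57
galizia,prodrome,noncardiac,no,117
iglesias,prodrome,cardiac,yes,79
iglesias,prodrome,cardiac,no,69
iglesias,prodrome,noncardiac,yes,611
iglesias,prodrome,noncardiac,no,180
alboni,blurred_vision,cardiac,yes,26
alboni,blurred_vision,cardiac,no,52
alboni,blurred_vision,noncardiac,yes,53
alboni,blurred_vision,noncardiac,no,206
calkins,blurred_vision,cardiac,yes,6
calkins,blurred_vision,cardiac,no,42
calkins,blurred_vision,noncardiac,yes,12
calkins,blurred_vision,noncardiac,no,20
delrosso_a,blurred_vision,cardiac,yes,30
delrosso_a,blurred_vision,cardiac,no,86
delrosso_a,blurred_vision,noncardiac,yes,31
delrosso_a,blurred_vision,noncardiac,no,265
delrosso_b,blurred_vision,cardiac,yes,8
delrosso_b,blurred_vision,cardiac,no,36
delrosso_b,blurred_vision,noncardiac,yes,68
delrosso_b,blurred_vision,noncardiac,no,148
galizia,blurred_vision,cardiac,yes,1
galizia,blurred_vision,cardiac,no,33
galizia,blurred_vision,noncardiac,yes,45
galizia,blurred_vision,noncardiac,no,129
iglesias,blurred_vision,cardiac,yes,26
iglesias,blurred_vision,cardiac,no,122
iglesias,blurred_vision,noncardiac,yes,308
iglesias,blurred_vision,noncardiac,no,483
alboni,palpitations,cardiac,yes,11
alboni,palpitations,cardiac,no,67
alboni,palpitations,noncardiac,yes,26
alboni,palpitations,noncardiac,no,233
calkins,palpitations,cardiac,yes,1
calkins,palpitations,cardiac,no,47
calkins,palpitations,noncardiac,yes,8
calkins,palpitations,noncardiac,no,24
delrosso_a,palpitations,cardiac,yes,13
delrosso_a,palpitations,cardiac,no,103
delrosso_a,palpitations,noncardiac,yes,38
delrosso_a,palpitations,noncardiac,no,258
delrosso_b,palpitations,cardiac,yes,4
delrosso_b,palpitations,cardiac,no,40
delrosso_b,palpitations,noncardiac,yes,2
delrosso_b,palpitations,noncardiac,no,214
galizia,palpitations,cardiac,yes,1
galizia,palpitations,cardiac,no,33
galizia,palpitations,noncardiac,yes,7
galizia,palpitations,noncardiac,no,167
iglesias,palpitations,cardiac,yes,9
iglesias,palpitations,cardiac,no,139
iglesias,palpitations,noncardiac,yes,119
iglesias,palpitations,noncardiac,no,672
alboni,supine_syncope,cardiac,yes,9
alboni,supine_syncope,cardiac,no,69
alboni,supine_syncope,noncardiac,yes,6
alboni,supine_syncope,noncardiac,no,253
calkins,supine_syncope,cardiac,yes,2
calkins,supine_syncope,cardiac,no,46
calkins,supine_syncope,noncardiac,yes,0
calkins,supine_syncope,noncardiac,no,32
delrosso_b,supine_syncope,cardiac,yes,6
delrosso_b,supine_syncope,cardiac,no,38
delrosso_b,supine_syncope,noncardiac,yes,6
delrosso_b,supine_syncope,noncardiac,no,210
alboni,effort_syncope,cardiac,yes,10
alboni,effort_syncope,cardiac,no,68
alboni,effort_syncope,noncardiac,yes,7
alboni,effort_syncope,noncardiac,no,252
delrosso_b,effort_syncope,cardiac,yes,6
delrosso_b,effort_syncope,cardiac,no,38
delrosso_b,effort_syncope,noncardiac,yes,2
delrosso_b,effort_syncope,noncardiac,no,214
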