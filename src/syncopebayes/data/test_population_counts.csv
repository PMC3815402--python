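population,predictor,class,level,count
calgary,age_category,cardiac,<40,7
calgary,age_category,cardiac,40-60,20
calgary,age_category,cardiac,>=60,111
calgary,age_category,noncardiac,<40,233
calgary,age_category,noncardiac,40-60,141
calgary,age_category,noncardiac,>=60,151
calgary,gender,cardiac,male,106
calgary,gender,cardiac,female,32
calgary,gender,noncardiac,male,246
calgary,gender,noncardiac,female,279
calgary,structural_heart_disease,cardiac,yes,81
calgary,structural_heart_disease,cardiac,no,49
calgary,structural_heart_disease,noncardiac,yes,62
calgary,structural_heart_disease,noncardiac,no,463
calgary,number_of_spells,cardiac,<=2,91
calgary,number_of_spells,cardiac,>2,47
calgary,number_of_spells,noncardiac,<=2,125
calgary,number_of_spells,noncardiac,>2,400
calgary,nausea,cardiac,yes,30
calgary,nausea,cardiac,no,108
calgary,nausea,noncardiac,yes,229
calgary,nausea,noncardiac,no,296
calgary,diaphoresis,cardiac,yes,52
calgary,diaphoresis,cardiac,no,86
calgary,diaphoresis,noncardiac,yes,266
calgary,diaphoresis,noncardiac,no,259
calgary,prodrome,cardiac,yes,36
calgary,prodrome,cardiac,no,101
calgary,prodrome,noncardiac,yes,271
calgary,prodrome,noncardiac,no,253
calgary,blurred_vision,cardiac,yes,33
calgary,blurred_vision,cardiac,no,105
calgary,blurred_vision,noncardiac,yes,215
calgary,blurred_vision,noncardiac,no,310
amsterdam,age_category,cardiac,<40,2
amsterdam,age_category,cardiac,40-60,10
amsterdam,age_category,cardiac,>=60,32
amsterdam,age_category,noncardiac,<40,143
amsterdam,age_category,noncardiac,40-60,148
amsterdam,age_category,noncardiac,>=60,128
amsterdam,gender,cardiac,male,35
amsterdam,gender,cardiac,female,9
amsterdam,gender,noncardiac,male,226
amsterdam,gender,noncardiac,female,193
amsterdam,structural_heart_disease,cardiac,yes,18
amsterdam,structural_heart_disease,cardiac,no,26
amsterdam,structural_heart_disease,noncardiac,yes,29
amsterdam,structural_heart_disease,noncardiac,no,390
amsterdam,number_of_spells,cardiac,<=2,26
amsterdam,number_of_spells,cardiac,>2,16
amsterdam,number_of_spells,noncardiac,<=2,151
amsterdam,number_of_spells,noncardiac,>2,218
amsterdam,nausea,cardiac,yes,6
amsterdam,nausea,cardiac,no,37
amsterdam,nausea,noncardiac,yes,129
amsterdam,nausea,noncardiac,no,287
amsterdam,diaphoresis,cardiac,yes,12
amsterdam,diaphoresis,cardiac,no,29
amsterdam,diaphoresis,noncardiac,yes,200
amsterdam,diaphoresis,noncardiac,no,216
amsterdam,prodrome,cardiac,yes,9
amsterdam,prodrome,cardiac,no,35
amsterdam,prodrome,noncardiac,yes,148
amsterdam,prodrome,noncardiac,no,271
amsterdam,effort_syncope,cardiac,yes,10
amsterdam,effort_syncope,cardiac,no,33
amsterdam,effort_syncope,noncardiac,yes,42
amsterdam,effort_syncope,noncardiac,no,365
milan,age_category,cardiac,<40,0
milan,age_category,cardiac,40-60,4
milan,age_category,cardiac,>=60,33
milan,age_category,noncardiac,<40,161
milan,age_category,noncardiac,40-60,137
milan,age_category,noncardiac,>=60,354
milan,gender,cardiac,male,22
milan,gender,cardiac,female,9
milan,gender,noncardiac,male,272
milan,gender,noncardiac,female,367
milan,structural_heart_disease,cardiac,yes,16
milan,structural_heart_disease,cardiac,no,21
milan,structural_heart_disease,noncardiac,yes,158
milan,structural_heart_disease,noncardiac,no,494
milan,number_of_spells,cardiac,<=2,23
milan,number_of_spells,cardiac,>2,14
milan,number_of_spells,noncardiac,<=2,370
milan,number_of_spells,noncardiac,>2,282
milan,prodrome,cardiac,yes,19
milan,prodrome,cardiac,no,18
milan,prodrome,noncardiac,yes,475
milan,prodrome,noncardiac,no,177
milan,supine_syncope,cardiac,yes,14
milan,supine_syncope,cardiac,no,23
milan,supine_syncope,noncardiac,yes,149
milan,supine_syncope,noncardiac,no,503
milan,effort_syncope,cardiac,yes,0
milan,effort_syncope,cardiac,no,37
milan,effort_syncope,noncardiac,yes,15
milan,effort_syncope,noncardiac,no,637
rochester,age_category,cardiac,<40,39
rochester,age_category,cardiac,40-60,48
rochester,age_category,cardiac,>=60,337
rochester,age_category,noncardiac,<40,967
rochester,age_category,noncardiac,40-60,648
rochester,age_category,noncardiac,>=60,1838
rochester,gender,cardiac,male,256
rochester,gender,cardiac,female,168
rochester,gender,noncardiac,male,1648
rochester,gender,noncardiac,female,1805
rochester,structural_heart_disease,cardiac,yes,135
rochester,structural_heart_disease,cardiac,no,289
rochester,structural_heart_disease,noncardiac,yes,279
rochester,structural_heart_disease,noncardiac,no,3174
rochester,number_of_spells,cardiac,<=2,262
rochester,number_of_spells,cardiac,>2,162
rochester,number_of_spells,noncardiac,<=2,2283
rochester,number_of_spells,noncardiac,>2,1170
rochester,nausea,cardiac,yes,64
rochester,nausea,cardiac,no,360
rochester,nausea,noncardiac,yes,808
rochester,nausea,noncardiac,no,2645
rochester,diaphoresis,cardiac,yes,91
rochester,diaphoresis,cardiac,no,333
rochester,diaphoresis,noncardiac,yes,814
rochester,diaphoresis,noncardiac,no,2639
rochester,prodrome,cardiac,yes,340
rochester,prodrome,cardiac,no,52
rochester,prodrome,noncardiac,yes,2976
rochester,prodrome,noncardiac,no,230
rochester,blurred_vision,cardiac,yes,6
rochester,blurred_vision,cardiac,no,418
rochester,blurred_vision,noncardiac,yes,92
rochester,blurred_vision,noncardiac,no,3361
rochester,supine_syncope,cardiac,yes,47
rochester,supine_syncope,cardiac,no,377
rochester,supine_syncope,noncardiac,yes,341
rochester,supine_syncope,noncardiac,no,3112
rochester,effort_syncope,cardiac,yes,69
rochester,effort_syncope,cardiac,no,355
rochester,effort_syncope,noncardiac,yes,363
rochester,effort_syncope,noncardiac,no,3090
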