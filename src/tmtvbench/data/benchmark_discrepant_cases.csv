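case_id,subtype,stage,reader_id,tmtv_cm3,note_category,adjudicator_note
H15,HL,4,1,275,spleen,Spleen
H15,HL,4,2,129,spleen,Spleen
H15,HL,4,3,282,spleen,Spleen
F02,FL,4,1,426,spleen,Spleen
F02,FL,4,2,399,spleen,Spleen
F02,FL,4,3,456,spleen,Spleen
F02,FL,4,4,252,spleen,Spleen
F05,FL,4,1,1680,spleen,Spleen
F05,FL,4,2,1706,spleen,Spleen
F05,FL,4,3,1650,spleen,Spleen
F05,FL,4,4,567,spleen,Spleen
B10,DLBCL,4,1,786,spleen,Spleen
B10,DLBCL,4,2,788,spleen,Spleen
B10,DLBCL,4,3,49,spleen,Spleen
B16,DLBCL,4,1,1223,spleen,Spleen
B16,DLBCL,4,2,546,spleen,Spleen
B16,DLBCL,4,3,509,spleen,Spleen
H11,HL,4,1,178,other,Physiologic uptake removed = 139 cm3; manual addition of small multifocal uptake in BM neck and retroperitoneal increased to 231 cm3
H11,HL,4,2,229,other,Physiologic uptake removed = 139 cm3; manual addition of small multifocal uptake in BM neck and retroperitoneal increased to 231 cm3
H11,HL,4,3,137,other,Physiologic uptake removed = 139 cm3; manual addition of small multifocal uptake in BM neck and retroperitoneal increased to 231 cm3
H11,HL,4,4,159,other,Physiologic uptake removed = 139 cm3; manual addition of small multifocal uptake in BM neck and retroperitoneal increased to 231 cm3
B05,DLBCL,4,1,272,other,Manual editing of myocardial uptake
B05,DLBCL,4,2,321,other,Manual editing of myocardial uptake
B05,DLBCL,4,3,318,other,Manual editing of myocardial uptake
F09,FL,4,1,246,other,Manual editing of kidneys and ureter
F09,FL,4,2,194,other,Manual editing of kidneys and ureter
F09,FL,4,3,196,other,Manual editing of kidneys and ureter
F09,FL,4,4,199,other,Manual editing of kidneys and ureter
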