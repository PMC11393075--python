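class_or_concept,name
aki,acute kidney injury
aki,renal failure
aki,renal impairment
aki,oliguria
aki,anuria
aki,azotaemia
aki,prerenal failure
aki,blood creatinine increased
aki,glomerular filtration rate decreased
aki,renal tubular necrosis
ckd,chronic kidney disease
ckd,renal failure chronic
ckd,end stage renal disease
ckd,nephrosclerosis
ckd,dialysis
ckd,haemodialysis
ckd,peritoneal dialysis
hypertension,hypertension
hypertension,essential hypertension
hypertension,blood pressure increased
hypertension,hypertensive crisis
hypertension,renal hypertension
diabetes,diabetes mellitus
diabetes,type 2 diabetes mellitus
diabetes,type 1 diabetes mellitus
diabetes,hyperglycaemia
diabetes,glycosylated haemoglobin increased
diabetes,new onset diabetes mellitus
heart_failure,cardiac failure
heart_failure,cardiac failure congestive
heart_failure,cardiac failure chronic
heart_failure,cardiac failure acute
heart_failure,left ventricular failure
heart_failure,cardiogenic shock
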