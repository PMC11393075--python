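class_or_concept,name
active_vitamin_d3,eldecalcitol
active_vitamin_d3,alfacalcidol
active_vitamin_d3,calcitriol
nsaid,loxoprofen
nsaid,diclofenac
nsaid,ibuprofen
nsaid,naproxen
nsaid,celecoxib
nsaid,etodolac
nsaid,meloxicam
nsaid,indomethacin
nsaid,ketoprofen
nsaid,sulindac
rasi,enalapril
rasi,imidapril
rasi,lisinopril
rasi,perindopril
rasi,temocapril
rasi,candesartan
rasi,losartan
rasi,valsartan
rasi,telmisartan
rasi,olmesartan
rasi,azilsartan
rasi,irbesartan
loop_diuretic,furosemide
loop_diuretic,azosemide
loop_diuretic,torasemide
loop_diuretic,bumetanide
thiazide_like_diuretic,trichlormethiazide
thiazide_like_diuretic,hydrochlorothiazide
thiazide_like_diuretic,benzylhydrochlorothiazide
thiazide_like_diuretic,indapamide
thiazide_like_diuretic,mefruside
thiazide_like_diuretic,tripamide
magnesium_oxide,magnesium oxide
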