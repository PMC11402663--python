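drug,atc_class
LENALIDOMIDE,L
ADALIMUMAB,L
NIRAPARIB,L
ERENUMAB,N
SEVELAMER CARBONATE,V
TERIPARATIDE,H
PALBOCICLIB,L
PATIROMER,V
VARENICLINE,N
ORLISTAT,A
POMALIDOMIDE,L
OXYCODONE,N
DIMETHYL FUMARATE,N
ENZALUTAMIDE,L
EXENATIDE,A
CABOZANTINIB,L
CLOZAPINE,N
SEMAGLUTIDE,A
NINTEDANIB,L
SOLIFENACIN SUCCINATE,G
ALENDRONATE SODIUM,M
DALFAMPRIDINE,N
DULAGLUTIDE,A
PREGABALIN,N
ETANERCEPT,L
DULOXETINE HYDROCHLORIDE,N
CAPECITABINE,L
VEDOLIZUMAB,L
INFLIXIMAB,L
BEVACIZUMAB,L
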