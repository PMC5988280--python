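name,chem_class,method
C0,acylcarnitine,FIA
C2,acylcarnitine,FIA
C3,acylcarnitine,FIA
C3:1,acylcarnitine,FIA
C3-OH,acylcarnitine,FIA
C4,acylcarnitine,FIA
C4:1,acylcarnitine,FIA
C4-OH,acylcarnitine,FIA
C5,acylcarnitine,FIA
C5:1,acylcarnitine,FIA
C5:1-DC,acylcarnitine,FIA
C5-DC,acylcarnitine,FIA
C5-M-DC,acylcarnitine,FIA
C5-OH,acylcarnitine,FIA
C6,acylcarnitine,FIA
C6:1,acylcarnitine,FIA
C7-DC,acylcarnitine,FIA
C8,acylcarnitine,FIA
C9,acylcarnitine,FIA
C10,acylcarnitine,FIA
C10:1,acylcarnitine,FIA
C10:2,acylcarnitine,FIA
C12,acylcarnitine,FIA
C12:1,acylcarnitine,FIA
C12-DC,acylcarnitine,FIA
C14,acylcarnitine,FIA
C14:1,acylcarnitine,FIA
C14:1-OH,acylcarnitine,FIA
C14:2,acylcarnitine,FIA
C14:2-OH,acylcarnitine,FIA
C16,acylcarnitine,FIA
C16:1,acylcarnitine,FIA
C16:1-OH,acylcarnitine,FIA
C16:2,acylcarnitine,FIA
C16:2-OH,acylcarnitine,FIA
C16-OH,acylcarnitine,FIA
C18,acylcarnitine,FIA
C18:1,acylcarnitine,FIA
C18:1-OH,acylcarnitine,FIA
C18:2,acylcarnitine,FIA
Ala,amino_acid,LC
Arg,amino_acid,LC
Asn,amino_acid,LC
Asp,amino_acid,LC
Cit,amino_acid,LC
Gln,amino_acid,LC
Glu,amino_acid,LC
Gly,amino_acid,LC
His,amino_acid,LC
Ile,amino_acid,LC
Leu,amino_acid,LC
Lys,amino_acid,LC
Met,amino_acid,LC
Orn,amino_acid,LC
Phe,amino_acid,LC
Pro,amino_acid,LC
Ser,amino_acid,LC
Thr,amino_acid,LC
Trp,amino_acid,LC
Tyr,amino_acid,LC
Val,amino_acid,LC
Ac-Orn,biogenic_amine,LC
ADMA,biogenic_amine,LC
alpha-AAA,biogenic_amine,LC
Carnosine,biogenic_amine,LC
Creatinine,biogenic_amine,LC
DOPA,biogenic_amine,LC
Dopamine,biogenic_amine,LC
Histamine,biogenic_amine,LC
Kynurenine,biogenic_amine,LC
Met-SO,biogenic_amine,LC
Nitro-Tyr,biogenic_amine,LC
OH-Pro,biogenic_amine,LC
PEA,biogenic_amine,LC
Putrescine,biogenic_amine,LC
Sarcosine,biogenic_amine,LC
SDMA,biogenic_amine,LC
Serotonin,biogenic_amine,LC
Spermidine,biogenic_amine,LC
Spermine,biogenic_amine,LC
Taurine,biogenic_amine,LC
H1,hexose,LC
lysoPC a C14:0,lysoPC,FIA
lysoPC a C16:0,lysoPC,FIA
lysoPC a C16:1,lysoPC,FIA
lysoPC a C17:0,lysoPC,FIA
lysoPC a C18:0,lysoPC,FIA
lysoPC a C18:1,lysoPC,FIA
lysoPC a C18:2,lysoPC,FIA
lysoPC a C20:3,lysoPC,FIA
lysoPC a C20:4,lysoPC,FIA
lysoPC a C24:0,lysoPC,FIA
lysoPC a C26:0,lysoPC,FIA
lysoPC a C26:1,lysoPC,FIA
lysoPC a C28:0,lysoPC,FIA
lysoPC a C28:1,lysoPC,FIA
PC aa C24:0,PC_aa,FIA
PC aa C26:0,PC_aa,FIA
PC aa C28:1,PC_aa,FIA
PC aa C30:0,PC_aa,FIA
PC aa C30:2,PC_aa,FIA
PC aa C32:0,PC_aa,FIA
PC aa C32:1,PC_aa,FIA
PC aa C32:2,PC_aa,FIA
PC aa C32:3,PC_aa,FIA
PC aa C34:1,PC_aa,FIA
PC aa C34:2,PC_aa,FIA
PC aa C34:3,PC_aa,FIA
PC aa C34:4,PC_aa,FIA
PC aa C36:0,PC_aa,FIA
PC aa C36:1,PC_aa,FIA
PC aa C36:2,PC_aa,FIA
PC aa C36:3,PC_aa,FIA
PC aa C36:4,PC_aa,FIA
PC aa C36:5,PC_aa,FIA
PC aa C36:6,PC_aa,FIA
PC aa C38:0,PC_aa,FIA
PC aa C38:1,PC_aa,FIA
PC aa C38:3,PC_aa,FIA
PC aa C38:4,PC_aa,FIA
PC aa C38:5,PC_aa,FIA
PC aa C38:6,PC_aa,FIA
PC aa C40:1,PC_aa,FIA
PC aa C40:2,PC_aa,FIA
PC aa C40:3,PC_aa,FIA
PC aa C40:4,PC_aa,FIA
PC aa C40:5,PC_aa,FIA
PC aa C40:6,PC_aa,FIA
PC aa C42:0,PC_aa,FIA
PC aa C42:1,PC_aa,FIA
PC aa C42:2,PC_aa,FIA
PC aa C42:4,PC_aa,FIA
PC aa C42:5,PC_aa,FIA
PC aa C42:6,PC_aa,FIA
PC ae C30:0,PC_ae,FIA
PC ae C30:1,PC_ae,FIA
PC ae C30:2,PC_ae,FIA
PC ae C32:1,PC_ae,FIA
PC ae C32:2,PC_ae,FIA
PC ae C34:0,PC_ae,FIA
PC ae C34:1,PC_ae,FIA
PC ae C34:2,PC_ae,FIA
PC ae C34:3,PC_ae,FIA
PC ae C36:0,PC_ae,FIA
PC ae C36:1,PC_ae,FIA
PC ae C36:2,PC_ae,FIA
PC ae C36:3,PC_ae,FIA
PC ae C36:4,PC_ae,FIA
PC ae C36:5,PC_ae,FIA
PC ae C38:0,PC_ae,FIA
PC ae C38:1,PC_ae,FIA
PC ae C38:2,PC_ae,FIA
PC ae C38:3,PC_ae,FIA
PC ae C38:4,PC_ae,FIA
PC ae C38:5,PC_ae,FIA
PC ae C38:6,PC_ae,FIA
PC ae C40:1,PC_ae,FIA
PC ae C40:2,PC_ae,FIA
PC ae C40:3,PC_ae,FIA
PC ae C40:4,PC_ae,FIA
PC ae C40:5,PC_ae,FIA
PC ae C40:6,PC_ae,FIA
PC ae C42:0,PC_ae,FIA
PC ae C42:1,PC_ae,FIA
PC ae C42:2,PC_ae,FIA
PC ae C42:3,PC_ae,FIA
PC ae C42:4,PC_ae,FIA
PC ae C42:5,PC_ae,FIA
PC ae C44:3,PC_ae,FIA
PC ae C44:4,PC_ae,FIA
PC ae C44:5,PC_ae,FIA
PC ae C44:6,PC_ae,FIA
SM C16:0,SM,FIA
SM C16:1,SM,FIA
SM C18:0,SM,FIA
SM C18:1,SM,FIA
SM C20:2,SM,FIA
SM C22:0,SM,FIA
SM C22:3,SM,FIA
SM C24:0,SM,FIA
SM C24:1,SM,FIA
SM C26:0,SM,FIA
SM C26:1,SM,FIA
SM OH C14:1,SM_OH,FIA
SM OH C16:1,SM_OH,FIA
SM OH C22:1,SM_OH,FIA
SM OH C22:2,SM_OH,FIA
SM OH C24:1,SM_OH,FIA
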