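"""Embedded drug-like fixture set: ~200 named public-domain structures.

A deterministic, download-free stand-in for a purchasable drug-like
screening library; used to seed small searches and to measure operator
validity rates on realistic SMILES strings.
"""

DRUGLIKE_SMILES: list[tuple[str, str]] = [
    ('aspirin', 'CC(=O)Oc1ccccc1C(=O)O'),
    ('paracetamol', 'CC(=O)Nc1ccc(O)cc1'),
    ('ibuprofen', 'CC(C)Cc1ccc(C(C)C(=O)O)cc1'),
    ('naproxen', 'COc1ccc2cc(C(C)C(=O)O)ccc2c1'),
    ('caffeine', 'Cn1cnc2c1c(=O)n(C)c(=O)n2C'),
    ('nicotine', 'CN1CCCC1c1cccnc1'),
    ('benzocaine', 'CCOC(=O)c1ccc(N)cc1'),
    ('procaine', 'CCN(CC)CCOC(=O)c1ccc(N)cc1'),
    ('lidocaine', 'CCN(CC)CC(=O)Nc1c(C)cccc1C'),
    ('atenolol', 'CC(C)NCC(O)COc1ccc(CC(N)=O)cc1'),
    ('propranolol', 'CC(C)NCC(O)COc1cccc2ccccc12'),
    ('metoprolol', 'COCCc1ccc(OCC(O)CNC(C)C)cc1'),
    ('salbutamol', 'CC(C)(C)NCC(O)c1ccc(O)c(CO)c1'),
    ('warfarin', 'CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O'),
    ('diazepam', 'CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O'),
    ('alprazolam', 'Cc1nnc2CN=C(c3ccccc3)c3cc(Cl)ccc3-n12'),
    ('theophylline', 'Cn1c(=O)c2[nH]cnc2n(C)c1=O'),
    ('ciprofloxacin', 'O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O'),
    ('norfloxacin', 'CCn1cc(C(=O)O)c(=O)c2cc(F)c(N3CCNCC3)cc21'),
    ('sulfamethoxazole', 'Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1'),
    ('trimethoprim', 'COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC'),
    ('metronidazole', 'Cc1ncc([N+](=O)[O-])n1CCO'),
    ('fluconazole', 'OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F'),
    ('ketoconazole', 'CC(=O)N1CCN(c2ccc(OCC3COC(Cn4ccnc4)(c4ccc(Cl)cc4Cl)O3)cc2)CC1'),
    ('omeprazole', 'COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1'),
    ('ranitidine', 'CNC(=C[N+](=O)[O-])NCCSCc1ccc(CN(C)C)o1'),
    ('cimetidine', 'Cc1nc[nH]c1CSCCNC(=NC)NC#N'),
    ('loratadine', 'CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1'),
    ('cetirizine', 'OC(=O)COCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1'),
    ('diphenhydramine', 'CN(C)CCOC(c1ccccc1)c1ccccc1'),
    ('chlorpheniramine', 'CN(C)CCC(c1ccc(Cl)cc1)c1ccccn1'),
    ('fexofenadine', 'CC(C)(C(=O)O)c1ccc(C(O)CCCN2CCC(C(O)(c3ccccc3)c3ccccc3)CC2)cc1'),
    ('sertraline', 'CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21'),
    ('fluoxetine', 'CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1'),
    ('paroxetine', 'Fc1ccc(C2CCNCC2COc2ccc3c(c2)OCO3)cc1'),
    ('citalopram', 'CN(C)CCCC1(c2ccc(F)cc2)OCc2cc(C#N)ccc21'),
    ('venlafaxine', 'COc1ccc(C(CN(C)C)C2(O)CCCCC2)cc1'),
    ('bupropion', 'CC(NC(C)(C)C)C(=O)c1cccc(Cl)c1'),
    ('duloxetine', 'CNCCC(Oc1cccc2ccccc12)c1cccs1'),
    ('imipramine', 'CN(C)CCCN1c2ccccc2CCc2ccccc21'),
    ('amitriptyline', 'CN(C)CCC=C1c2ccccc2CCc2ccccc21'),
    ('haloperidol', 'O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1'),
    ('risperidone', 'Cc1nc2CCCCn2c(=O)c1CCN1CCC(c2noc3cc(F)ccc23)CC1'),
    ('olanzapine', 'Cc1cc2c(s1)Nc1ccccc1N=C2N1CCN(C)CC1'),
    ('quetiapine', 'OCCOCCN1CCN(C2=Nc3ccccc3Sc3ccccc32)CC1'),
    ('aripiprazole', 'O=C1CCc2cc(OCCCCN3CCN(c4cccc(Cl)c4Cl)CC3)ccc2N1'),
    ('clozapine', 'CN1CCN(C2=Nc3cc(Cl)ccc3Nc3ccccc32)CC1'),
    ('tramadol', 'COc1cccc(C2(O)CCCCC2CN(C)C)c1'),
    ('fentanyl', 'CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1'),
    ('methadone', 'CCC(=O)C(CC(C)N(C)C)(c1ccccc1)c1ccccc1'),
    ('celecoxib', 'Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1'),
    ('rofecoxib', 'CS(=O)(=O)c1ccc(C2=C(c3ccccc3)C(=O)OC2)cc1'),
    ('diclofenac', 'O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl'),
    ('indomethacin', 'COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1'),
    ('ketoprofen', 'CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1'),
    ('piroxicam', 'CN1C(C(=O)Nc2ccccn2)=C(O)c2ccccc2S1(=O)=O'),
    ('meloxicam', 'CN1C(C(=O)Nc2nc(C)cs2)=C(O)c2ccccc2S1(=O)=O'),
    ('atorvastatin', 'CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CCC(O)CC(O)CC(=O)O'),
    ('rosuvastatin', 'CC(C)c1nc(N(C)S(C)(=O)=O)nc(-c2ccc(F)cc2)c1C=CC(O)CC(O)CC(=O)O'),
    ('gemfibrozil', 'Cc1ccc(C)c(OCCCC(C)(C)C(=O)O)c1'),
    ('fenofibrate', 'CC(C)OC(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1'),
    ('metformin', 'CN(C)C(=N)NC(=N)N'),
    ('sitagliptin', 'NC(CC(=O)N1CCn2c(nnc2C(F)(F)F)C1)Cc1cc(F)c(F)cc1F'),
    ('pioglitazone', 'CCc1ccc(CCOc2ccc(CC3SC(=O)NC3=O)cc2)nc1'),
    ('rosiglitazone', 'CN(CCOc1ccc(CC2SC(=O)NC2=O)cc1)c1ccccn1'),
    ('losartan', 'CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1'),
    ('valsartan', 'CCCCC(=O)N(Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1)C(C(C)C)C(=O)O'),
    ('irbesartan', 'CCCCC1=NC2(CCCC2)C(=O)N1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1'),
    ('candesartan', 'CCOc1nc2cccc(C(=O)O)c2n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1'),
    ('amlodipine', 'CCOC(=O)C1=C(COCCN)NC(C)=C(C(=O)OC)C1c1ccccc1Cl'),
    ('nifedipine', 'COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]'),
    ('verapamil', 'COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC'),
    ('diltiazem', 'CC(=O)OC1C(c2ccc(OC)cc2)Sc2ccccc2N(CCN(C)C)C1=O'),
    ('lisinopril', 'NCCCCC(NC(CCc1ccccc1)C(=O)O)C(=O)N1CCCC1C(=O)O'),
    ('enalapril', 'CCOC(=O)C(CCc1ccccc1)NC(C)C(=O)N1CCCC1C(=O)O'),
    ('captopril', 'CC(CS)C(=O)N1CCCC1C(=O)O'),
    ('hydrochlorothiazide', 'NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O'),
    ('furosemide', 'NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl'),
    ('sildenafil', 'CCCc1nn(C)c2c(=O)[nH]c(-c3cc(S(=O)(=O)N4CCN(C)CC4)ccc3OCC)nc12'),
    ('tadalafil', 'CN1CC(=O)N2C(Cc3c([nH]c4ccccc34)C2c2ccc3c(c2)OCO3)C1=O'),
    ('oseltamivir', 'CCOC(=O)C1=CC(OC(CC)CC)C(NC(C)=O)C(N)C1'),
    ('amoxicillin', 'CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O'),
    ('ampicillin', 'CC1(C)SC2C(NC(=O)C(N)c3ccccc3)C(=O)N2C1C(=O)O'),
    ('penicillin_g', 'CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O'),
    ('cephalexin', 'CC1=C(C(=O)O)N2C(=O)C(NC(=O)C(N)c3ccccc3)C2SC1'),
    ('chloramphenicol', 'O=C(NC(CO)C(O)c1ccc([N+](=O)[O-])cc1)C(Cl)Cl'),
    ('isoniazid', 'NNC(=O)c1ccncc1'),
    ('ethambutol', 'CCC(CO)NCCNC(CC)CO'),
    ('pyrazinamide', 'NC(=O)c1cnccn1'),
    ('dapsone', 'Nc1ccc(S(=O)(=O)c2ccc(N)cc2)cc1'),
    ('chloroquine', 'CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12'),
    ('hydroxychloroquine', 'CCN(CCO)CCCC(C)Nc1ccnc2cc(Cl)ccc12'),
    ('quinine', 'COc1ccc2nccc(C(O)C3CC4CCN3CC4C=C)c2c1'),
    ('primaquine', 'COc1cc(NC(C)CCCN)c2ncccc2c1'),
    ('mefloquine', 'OC(C1CCCCN1)c1cc(C(F)(F)F)nc2c(C(F)(F)F)cccc12'),
    ('albendazole', 'CCCSc1ccc2[nH]c(NC(=O)OC)nc2c1'),
    ('mebendazole', 'COC(=O)Nc1nc2cc(C(=O)c3ccccc3)ccc2[nH]1'),
    ('levodopa', 'NC(Cc1ccc(O)c(O)c1)C(=O)O'),
    ('carbidopa', 'CC(Cc1ccc(O)c(O)c1)(NN)C(=O)O'),
    ('dopamine', 'NCCc1ccc(O)c(O)c1'),
    ('serotonin', 'NCCc1c[nH]c2ccc(O)cc12'),
    ('melatonin', 'COc1ccc2[nH]cc(CCNC(C)=O)c2c1'),
    ('histamine', 'NCCc1c[nH]cn1'),
    ('epinephrine', 'CNCC(O)c1ccc(O)c(O)c1'),
    ('phenylephrine', 'CNCC(O)c1cccc(O)c1'),
    ('pseudoephedrine', 'CNC(C)C(O)c1ccccc1'),
    ('amphetamine', 'CC(N)Cc1ccccc1'),
    ('methylphenidate', 'COC(=O)C(c1ccccc1)C1CCCCN1'),
    ('modafinil', 'NC(=O)CS(=O)C(c1ccccc1)c1ccccc1'),
    ('donepezil', 'COc1cc2c(cc1OC)C(=O)C(CC1CCN(Cc3ccccc3)CC1)C2'),
    ('memantine', 'CC12CC3CC(C)(C1)CC(N)(C3)C2'),
    ('rivastigmine', 'CCN(C)C(=O)Oc1cccc(C(C)N(C)C)c1'),
    ('gabapentin', 'NCC1(CC(=O)O)CCCCC1'),
    ('pregabalin', 'CC(C)CC(CN)CC(=O)O'),
    ('carbamazepine', 'NC(=O)N1c2ccccc2C=Cc2ccccc21'),
    ('oxcarbazepine', 'NC(=O)N1c2ccccc2CC(=O)c2ccccc21'),
    ('phenytoin', 'O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1'),
    ('valproic_acid', 'CCCC(CCC)C(=O)O'),
    ('lamotrigine', 'Nc1nnc(-c2cccc(Cl)c2Cl)c(N)n1'),
    ('levetiracetam', 'CCC(C(N)=O)N1CCCC1=O'),
    ('zolpidem', 'Cc1ccc(-c2nc3ccc(C)cn3c2CC(=O)N(C)C)cc1'),
    ('buspirone', 'O=C1CC2(CCCC2)CC(=O)N1CCCCN1CCN(c2ncccn2)CC1'),
    ('ondansetron', 'Cc1nccn1CC1CCc2c(C1=O)c1ccccc1n2C'),
    ('sumatriptan', 'CNS(=O)(=O)Cc1ccc2[nH]cc(CCN(C)C)c2c1'),
    ('rizatriptan', 'CN(C)CCc1c[nH]c2ccc(Cn3cncn3)cc12'),
    ('cocaine', 'COC(=O)C1C(OC(=O)c2ccccc2)CC2CCC1N2C'),
    ('atropine', 'CN1C2CCC1CC(OC(=O)C(CO)c1ccccc1)C2'),
    ('testosterone', 'CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O'),
    ('estradiol', 'CC12CCC3c4ccc(O)cc4CCC3C1CCC2O'),
    ('progesterone', 'CC(=O)C1CCC2C3CCC4=CC(=O)CCC4(C)C3CCC12C'),
    ('tamoxifen', 'CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1'),
    ('letrozole', 'N#Cc1ccc(C(c2ccc(C#N)cc2)n2cncn2)cc1'),
    ('anastrozole', 'CC(C)(C#N)c1cc(Cn2cncn2)cc(C(C)(C)C#N)c1'),
    ('imatinib', 'Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1'),
    ('gefitinib', 'COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1'),
    ('erlotinib', 'COCCOc1cc2ncnc(Nc3cccc(C#C)c3)c2cc1OCCOC'),
    ('sorafenib', 'CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1'),
    ('sunitinib', 'CCN(CC)CCNC(=O)c1c(C)[nH]c(C=C2C(=O)Nc3ccc(F)cc32)c1C'),
    ('dasatinib', 'Cc1nc(Nc2ncc(C(=O)Nc3c(C)cccc3Cl)s2)cc(N2CCN(CCO)CC2)n1'),
    ('fluorouracil', 'O=c1[nH]cc(F)c(=O)[nH]1'),
    ('methotrexate', 'CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc1'),
    ('cyclophosphamide', 'O=P1(N(CCCl)CCCl)NCCCO1'),
    ('thalidomide', 'O=C1CCC(N2C(=O)c3ccccc3C2=O)C(=O)N1'),
    ('lenalidomide', 'Nc1cccc2c1CN(C1CCC(=O)NC1=O)C2=O'),
    ('colchicine', 'COc1cc2c(c(OC)c1OC)-c1ccc(OC)c(=O)cc1C(NC(C)=O)CC2'),
    ('probenecid', 'CCCN(CCC)S(=O)(=O)c1ccc(C(=O)O)cc1'),
    ('theobromine', 'Cn1cnc2c1c(=O)[nH]c(=O)n2C'),
    ('pentoxifylline', 'CC(=O)CCCCn1c(=O)c2c(ncn2C)n(C)c1=O'),
    ('clopidogrel', 'COC(=O)C(c1ccccc1Cl)N1CCc2sccc2C1'),
    ('ticlopidine', 'Clc1ccccc1CN1CCc2sccc2C1'),
    ('rivaroxaban', 'O=C(NCC1CN(c2ccc(N3CCOCC3=O)cc2)C(=O)O1)c1ccc(Cl)s1'),
    ('phenprocoumon', 'CCC(c1ccccc1)c1c(O)c2ccccc2oc1=O'),
    ('folic_acid', 'Nc1nc2ncc(CNc3ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc3)nc2c(=O)[nH]1'),
    ('pyridoxine', 'Cc1ncc(CO)c(CO)c1O'),
    ('nicotinic_acid', 'O=C(O)c1cccnc1'),
    ('ascorbic_acid', 'OCC(O)C1OC(=O)C(O)=C1O'),
    ('biotin', 'O=C1NC2C(CCCCC(=O)O)SCC2N1'),
    ('menadione', 'CC1=CC(=O)c2ccccc2C1=O'),
    ('chlorzoxazone', 'O=c1[nH]c2cc(Cl)ccc2o1'),
    ('baclofen', 'NCC(CC(=O)O)c1ccc(Cl)cc1'),
    ('cyclobenzaprine', 'CN(C)CCC=C1c2ccccc2C=Cc2ccccc21'),
    ('orphenadrine', 'CN(C)CCOC(c1ccccc1)c1ccccc1C'),
    ('tolbutamide', 'CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1'),
    ('metoclopramide', 'CCN(CC)CCNC(=O)c1cc(Cl)c(N)cc1OC'),
    ('pantoprazole', 'COc1ccnc(CS(=O)c2nc3cc(OC(F)F)ccc3[nH]2)c1OC'),
    ('lansoprazole', 'Cc1c(OCC(F)(F)F)ccnc1CS(=O)c1nc2ccccc2[nH]1'),
    ('bisacodyl', 'CC(=O)Oc1ccc(C(c2ccccn2)c2ccc(OC(C)=O)cc2)cc1'),
    ('loperamide', 'CN(C)C(=O)C(CCN1CCC(O)(c2ccc(Cl)cc2)CC1)(c1ccccc1)c1ccccc1'),
    ('prazosin', 'COc1cc2nc(N3CCN(C(=O)c4ccco4)CC3)nc(N)c2cc1OC'),
    ('terazosin', 'COc1cc2nc(N3CCN(C(=O)C4CCCO4)CC3)nc(N)c2cc1OC'),
    ('clonidine', 'Clc1cccc(Cl)c1NC1=NCCN1'),
    ('tamsulosin', 'CCOc1ccccc1OCCNC(C)Cc1ccc(OC)c(S(N)(=O)=O)c1'),
    ('oxybutynin', 'CCN(CC)CC#CCOC(=O)C(O)(c1ccccc1)C1CCCCC1'),
    ('niacinamide', 'NC(=O)c1cccnc1'),
    ('salicylic_acid', 'O=C(O)c1ccccc1O'),
    ('mandelic_acid', 'OC(C(=O)O)c1ccccc1'),
    ('allopurinol', 'O=c1[nH]cnc2[nH]ncc12'),
    ('aciclovir', 'Nc1nc2c(ncn2COCCO)c(=O)[nH]1'),
    ('zidovudine', 'Cc1cn(C2CC(N=[N+]=[N-])C(CO)O2)c(=O)[nH]c1=O'),
    ('minoxidil', 'Nc1cc(N2CCCCC2)[n+]([O-])c(N)n1'),
    ('montelukast_frag', 'CC(C)(O)c1ccccc1CCC(SCC1(CC(=O)O)CC1)c1cccc(C=Cc2ccc3ccc(Cl)cc3n2)c1'),
    ('glibenclamide', 'COc1ccc(Cl)cc1C(=O)NCCc1ccc(S(=O)(=O)NC(=O)NC2CCCCC2)cc1'),
    ('repaglinide', 'CCOc1cc(CC(=O)NC(CC(C)C)c2ccccc2N2CCCCC2)ccc1C(=O)O'),
    ('nateglinide', 'CC(C)C1CCC(C(=O)NC(Cc2ccccc2)C(=O)O)CC1'),
    ('telmisartan', 'CCCc1nc2c(C)cc(-c3nc4ccccc4n3C)cc2n1Cc1ccc(-c2ccccc2C(=O)O)cc1'),
    ('ezetimibe_frag', 'OC(CCC1C(=O)N(c2ccc(F)cc2)C1c1ccc(O)cc1)c1ccc(F)cc1'),
    ('apigenin', 'O=c1cc(-c2ccc(O)cc2)oc2cc(O)cc(O)c12'),
    ('quercetin', 'O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12'),
    ('resveratrol', 'Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1'),
    ('curcumin', 'COc1cc(C=CC(=O)CC(=O)C=Cc2ccc(O)c(OC)c2)ccc1O'),
    ('vanillin', 'COc1cc(C=O)ccc1O'),
    ('coumarin', 'O=c1ccc2ccccc2o1'),
    ('papaverine', 'COc1ccc(Cc2nccc3cc(OC)c(OC)cc23)cc1OC'),
    ('hydroxyzine', 'OCCOCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1'),
    ('meclizine', 'Cc1cccc(CN2CCN(C(c3ccccc3)c3ccc(Cl)cc3)CC2)c1'),
    ('ketamine', 'CNC1(c2ccccc2Cl)CCCCC1=O'),
    ('propofol', 'CC(C)c1cccc(C(C)C)c1O'),
    ('etomidate', 'CCOC(=O)c1cncn1C(C)c1ccccc1'),
    ('midazolam', 'Cc1ncc2CN=C(c3ccccc3F)c3cc(Cl)ccc3-n12'),
    ('flumazenil', 'CCOC(=O)c1ncn2c1CN(C)C(=O)c1cc(F)ccc12'),
]
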