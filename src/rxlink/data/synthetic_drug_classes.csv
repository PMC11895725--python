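rxcui,ingredient,drug_class
36437,sertraline,SSRI
4493,fluoxetine,SSRI
321988,escitalopram,SSRI
2556,citalopram,SSRI
32937,paroxetine,SSRI
42355,fluvoxamine,SSRI
39786,venlafaxine,SNRI
72625,duloxetine,SNRI
42347,bupropion,atypical_antidepressant
15996,mirtazapine,atypical_antidepressant
10737,trazodone,atypical_antidepressant
6901,methylphenidate,stimulant
725,amphetamine,stimulant
38400,atomoxetine,nonstimulant_adhd
5021,guanfacine,alpha_agonist
2599,clonidine,alpha_agonist
89013,aripiprazole,antipsychotic
35636,risperidone,antipsychotic
51272,quetiapine,antipsychotic
5553,hydroxyzine,anxiolytic
6470,lorazepam,benzodiazepine
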