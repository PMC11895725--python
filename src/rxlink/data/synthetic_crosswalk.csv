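rxcui,ndc,drug_name
36437,00049-4960-30,sertraline 25 MG oral tablet
36437,00049-4961-50,sertraline 50 MG oral tablet
4493,00777-3105-02,fluoxetine 10 MG oral capsule
4493,00777-3107-30,fluoxetine 20 MG oral capsule
321988,00456-2005-01,escitalopram 5 MG oral tablet
321988,00456-2010-01,escitalopram 10 MG oral tablet
2556,00093-7112-98,citalopram 10 MG oral tablet
2556,00093-7113-98,citalopram 20 MG oral tablet
32937,00029-3210-13,paroxetine 10 MG oral tablet
32937,00029-3211-13,paroxetine 20 MG oral tablet
42355,00378-5025-93,fluvoxamine 25 MG oral tablet
42355,00378-5050-93,fluvoxamine 50 MG oral tablet
39786,00008-0833-01,venlafaxine 37.5 MG extended release capsule
39786,00008-0836-01,venlafaxine 75 MG extended release capsule
72625,00002-3235-30,duloxetine 20 MG delayed release capsule
72625,00002-3240-30,duloxetine 30 MG delayed release capsule
42347,00093-5385-56,bupropion 75 MG oral tablet
42347,00093-5386-56,bupropion 100 MG oral tablet
15996,00052-0105-30,mirtazapine 15 MG oral tablet
15996,00052-0107-30,mirtazapine 30 MG oral tablet
10737,50111-0441-01,trazodone 50 MG oral tablet
10737,50111-0442-01,trazodone 100 MG oral tablet
6901,00406-1121-01,methylphenidate 5 MG oral tablet
6901,00406-1122-01,methylphenidate 10 MG oral tablet
38400,00002-3227-30,atomoxetine 10 MG oral capsule
38400,00002-3228-30,atomoxetine 18 MG oral capsule
5021,59651-0337-30,guanfacine 1 MG extended release tablet
5021,59651-0338-30,guanfacine 2 MG extended release tablet
2599,00093-0031-01,clonidine 0.1 MG oral tablet
2599,00093-0032-01,clonidine 0.2 MG oral tablet
89013,59148-0006-13,aripiprazole 2 MG oral tablet
89013,59148-0007-13,aripiprazole 5 MG oral tablet
35636,50458-0300-06,risperidone 0.25 MG oral tablet
35636,50458-0301-06,risperidone 0.5 MG oral tablet
51272,00310-0271-10,quetiapine 25 MG oral tablet
51272,00310-0272-10,quetiapine 50 MG oral tablet
5553,00069-5410-66,hydroxyzine 10 MG oral tablet
5553,00069-5420-66,hydroxyzine 25 MG oral tablet
6470,00187-0063-01,lorazepam 0.5 MG oral tablet
6470,00187-0064-01,lorazepam 1 MG oral tablet
725,57844-0112-01,amphetamine 5 MG oral tablet
725,57844-0115-01,amphetamine 10 MG oral tablet
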