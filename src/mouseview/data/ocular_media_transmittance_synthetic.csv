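# Synthetic stand-in for whole-eye ocular media transmittance
# (logistic short-pass absorber, half point 330 nm); relative units.
wavelength_nm,value
300,0.158869
302,0.174285
304,0.190858
306,0.208609
308,0.227546
310,0.247664
312,0.268941
314,0.291339
316,0.314799
318,0.339244
320,0.364576
322,0.390682
324,0.41743
326,0.444672
328,0.472251
330,0.5
332,0.527749
334,0.555328
336,0.58257
338,0.609318
340,0.635424
342,0.660756
344,0.685201
346,0.708661
348,0.731059
350,0.752336
352,0.772454
354,0.791391
356,0.809142
358,0.825715
360,0.841131
362,0.855422
364,0.868629
366,0.880797
368,0.891978
370,0.902227
372,0.9116
374,0.920154
376,0.927946
378,0.935031
380,0.941463
382,0.947294
384,0.952574
386,0.957349
388,0.961662
390,0.965555
392,0.969065
394,0.972228
396,0.975076
398,0.977638
400,0.979942
402,0.982014
404,0.983875
406,0.985546
408,0.987046
410,0.988393
412,0.989601
414,0.990684
416,0.991656
418,0.992526
420,0.993307
422,0.994007
424,0.994634
426,0.995195
428,0.995698
430,0.996149
432,0.996553
434,0.996914
436,0.997238
438,0.997527
440,0.997787
442,0.998019
444,0.998227
446,0.998413
448,0.99858
450,0.998729
452,0.998862
454,0.998982
456,0.999089
458,0.999185
460,0.99927
462,0.999347
464,0.999416
466,0.999477
468,0.999532
470,0.999581
472,0.999625
474,0.999665
476,0.9997
478,0.999731
480,0.99976
482,0.999785
484,0.999808
486,0.999828
488,0.999846
490,0.999862
492,0.999877
494,0.99989
496,0.999901
498,0.999912
500,0.999921
502,0.999929
504,0.999937
506,0.999943
508,0.999949
510,0.999955
512,0.999959
514,0.999964
516,0.999967
518,0.999971
520,0.999974
522,0.999977
524,0.999979
526,0.999981
528,0.999983
530,0.999985
532,0.999987
534,0.999988
536,0.999989
538,0.99999
540,0.999991
542,0.999992
544,0.999993
546,0.999994
548,0.999995
550,0.999995
552,0.999996
554,0.999996
556,0.999996
558,0.999997
560,0.999997
562,0.999997
564,0.999998
566,0.999998
568,0.999998
570,0.999998
572,0.999999
574,0.999999
576,0.999999
578,0.999999
580,0.999999
582,0.999999
584,0.999999
586,0.999999
588,0.999999
590,0.999999
592,1
594,1
596,1
598,1
600,1
602,1
604,1
606,1
608,1
610,1
612,1
614,1
616,1
618,1
620,1
622,1
624,1
626,1
628,1
630,1
632,1
634,1
636,1
638,1
640,1
642,1
644,1
646,1
648,1
650,1
652,1
654,1
656,1
658,1
660,1
662,1
664,1
666,1
668,1
670,1
672,1
674,1
676,1
678,1
680,1
682,1
684,1
686,1
688,1
690,1
692,1
694,1
696,1
698,1
700,1
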