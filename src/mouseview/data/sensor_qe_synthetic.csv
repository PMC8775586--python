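# Synthetic stand-in for a camera sensor quantum-efficiency curve
# (broad Gaussian, peak 520 nm, sigma 120 nm); relative units.
wavelength_nm,value
300,0.18627
302,0.192023
304,0.197899
306,0.203897
308,0.210019
310,0.216265
312,0.222635
314,0.229129
316,0.235746
318,0.242487
320,0.249352
322,0.25634
324,0.263451
326,0.270683
328,0.278037
330,0.285512
332,0.293106
334,0.300818
336,0.308647
338,0.316593
340,0.324652
342,0.332825
344,0.341108
346,0.349501
348,0.358
350,0.366604
352,0.375311
354,0.384118
356,0.393022
358,0.402021
360,0.411112
362,0.420292
364,0.429557
366,0.438905
368,0.448332
370,0.457833
372,0.467407
374,0.477048
376,0.486752
378,0.496516
380,0.506336
382,0.516206
384,0.526122
386,0.53608
388,0.546074
390,0.556101
392,0.566154
394,0.576229
396,0.58632
398,0.596423
400,0.606531
402,0.616639
404,0.626741
406,0.636832
408,0.646905
410,0.656956
412,0.666977
414,0.676963
416,0.686908
418,0.696805
420,0.706648
422,0.716432
424,0.726149
426,0.735794
428,0.745359
430,0.75484
432,0.764228
434,0.773519
436,0.782705
438,0.79178
440,0.800737
442,0.809572
444,0.818276
446,0.826844
448,0.83527
450,0.843548
452,0.851671
454,0.859633
456,0.867428
458,0.875052
460,0.882497
462,0.889758
464,0.89683
466,0.903707
468,0.910384
470,0.916855
472,0.923116
474,0.929162
476,0.934987
478,0.940588
480,0.945959
482,0.951097
484,0.955997
486,0.960656
488,0.965069
490,0.969233
492,0.973145
494,0.976801
496,0.980199
498,0.983335
500,0.986207
502,0.988813
504,0.991151
506,0.993218
508,0.995012
510,0.996534
512,0.99778
514,0.998751
516,0.999445
518,0.999861
520,1
522,0.999861
524,0.999445
526,0.998751
528,0.99778
530,0.996534
532,0.995012
534,0.993218
536,0.991151
538,0.988813
540,0.986207
542,0.983335
544,0.980199
546,0.976801
548,0.973145
550,0.969233
552,0.965069
554,0.960656
556,0.955997
558,0.951097
560,0.945959
562,0.940588
564,0.934987
566,0.929162
568,0.923116
570,0.916855
572,0.910384
574,0.903707
576,0.89683
578,0.889758
580,0.882497
582,0.875052
584,0.867428
586,0.859633
588,0.851671
590,0.843548
592,0.83527
594,0.826844
596,0.818276
598,0.809572
600,0.800737
602,0.79178
604,0.782705
606,0.773519
608,0.764228
610,0.75484
612,0.745359
614,0.735794
616,0.726149
618,0.716432
620,0.706648
622,0.696805
624,0.686908
626,0.676963
628,0.666977
630,0.656956
632,0.646905
634,0.636832
636,0.626741
638,0.616639
640,0.606531
642,0.596423
644,0.58632
646,0.576229
648,0.566154
650,0.556101
652,0.546074
654,0.53608
656,0.526122
658,0.516206
660,0.506336
662,0.496516
664,0.486752
666,0.477048
668,0.467407
670,0.457833
672,0.448332
674,0.438905
676,0.429557
678,0.420292
680,0.411112
682,0.402021
684,0.393022
686,0.384118
688,0.375311
690,0.366604
692,0.358
694,0.349501
696,0.341108
698,0.332825
700,0.324652
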