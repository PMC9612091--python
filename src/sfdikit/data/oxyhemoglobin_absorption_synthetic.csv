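# Oxyhemoglobin absorption coefficient, mm^-1 at 1 uM.
# Converted from molar extinction as ln(10)*eps*1e-6*0.1.
# SYNTHETIC fixture: monotone-cubic construction through anchor points
# at standard NIR absorption-feature positions; not a literature table.
# Generated by scripts/make_fixture_spectra.py.
wavelength_nm,value
650,0.00847351
651,0.00837815
652,0.00828375
653,0.00819046
654,0.00809845
655,0.00800788
656,0.0079189
657,0.00783168
658,0.00774638
659,0.00766315
660,0.00758216
661,0.00750356
662,0.00742751
663,0.00735418
664,0.00728373
665,0.0072163
666,0.00715207
667,0.00709119
668,0.00703383
669,0.00698013
670,0.00693027
671,0.0068844
672,0.00684268
673,0.00680527
674,0.00677233
675,0.00674402
676,0.00672049
677,0.00670192
678,0.00668846
679,0.00668026
680,0.0066775
681,0.0066775
682,0.0066775
683,0.0066775
684,0.0066775
685,0.0066775
686,0.0066775
687,0.0066775
688,0.0066775
689,0.0066775
690,0.0066775
691,0.0066775
692,0.0066775
693,0.0066775
694,0.0066775
695,0.0066775
696,0.0066775
697,0.0066775
698,0.0066775
699,0.0066775
700,0.0066775
701,0.00668168
702,0.006694
703,0.00671413
704,0.00674173
705,0.00677646
706,0.00681799
707,0.00686598
708,0.00692009
709,0.00697999
710,0.00704535
711,0.00711582
712,0.00719108
713,0.00727077
714,0.00735458
715,0.00744216
716,0.00753318
717,0.00762729
718,0.00772418
719,0.00782349
720,0.00792489
721,0.00802805
722,0.00813263
723,0.00823829
724,0.00834471
725,0.00845153
726,0.00855843
727,0.00866507
728,0.00877112
729,0.00887624
730,0.00898008
731,0.0090875
732,0.0092031
733,0.00932623
734,0.00945623
735,0.00959241
736,0.00973414
737,0.00988073
738,0.0100315
739,0.0101859
740,0.0103431
741,0.0105025
742,0.0106635
743,0.0108253
744,0.0109874
745,0.0111491
746,0.0113096
747,0.0114684
748,0.0116247
749,0.0117779
750,0.0119274
751,0.0120752
752,0.0122239
753,0.0123735
754,0.0125236
755,0.0126744
756,0.0128257
757,0.0129773
758,0.0131293
759,0.0132814
760,0.0134337
761,0.0135859
762,0.0137381
763,0.01389
764,0.0140417
765,0.0141929
766,0.0143437
767,0.0144939
768,0.0146434
769,0.0147921
770,0.01494
771,0.0150868
772,0.0152326
773,0.0153772
774,0.0155206
775,0.0156625
776,0.015803
777,0.0159419
778,0.0160792
779,0.0162147
780,0.0163484
781,0.0164802
782,0.0166105
783,0.0167394
784,0.0168668
785,0.0169929
786,0.0171179
787,0.0172417
788,0.0173645
789,0.0174863
790,0.0176073
791,0.0177275
792,0.017847
793,0.0179659
794,0.0180843
795,0.0182023
796,0.01832
797,0.0184374
798,0.0185547
799,0.0186719
800,0.0187891
801,0.0189067
802,0.019025
803,0.0191439
804,0.0192633
805,0.0193833
806,0.0195036
807,0.0196244
808,0.0197455
809,0.0198668
810,0.0199884
811,0.0201101
812,0.0202319
813,0.0203537
814,0.0204755
815,0.0205973
816,0.0207188
817,0.0208402
818,0.0209614
819,0.0210822
820,0.0212027
821,0.0213228
822,0.0214423
823,0.0215613
824,0.0216798
825,0.0217976
826,0.0219146
827,0.0220309
828,0.0221464
829,0.022261
830,0.0223746
831,0.0224873
832,0.0225989
833,0.0227093
834,0.0228186
835,0.0229267
836,0.0230335
837,0.0231389
838,0.023243
839,0.0233456
840,0.0234467
841,0.0235462
842,0.023644
843,0.0237402
844,0.0238346
845,0.0239273
846,0.024018
847,0.0241069
848,0.0241938
849,0.0242786
850,0.0243614
851,0.0244435
852,0.0245266
853,0.0246104
854,0.0246949
855,0.0247801
856,0.0248657
857,0.0249517
858,0.0250379
859,0.0251244
860,0.0252109
861,0.0252975
862,0.0253839
863,0.02547
864,0.0255559
865,0.0256414
866,0.0257263
867,0.0258106
868,0.0258942
869,0.0259769
870,0.0260588
871,0.0261396
872,0.0262193
873,0.0262977
874,0.0263749
875,0.0264506
876,0.0265248
877,0.0265973
878,0.0266681
879,0.0267371
880,0.0268042
881,0.0268692
882,0.0269321
883,0.0269928
884,0.0270511
885,0.027107
886,0.0271604
887,0.0272111
888,0.0272591
889,0.0273043
890,0.0273465
891,0.0273857
892,0.0274217
893,0.0274545
894,0.027484
895,0.02751
896,0.0275325
897,0.0275513
898,0.0275664
899,0.0275777
900,0.027585
901,0.0275902
902,0.0275954
903,0.0276004
904,0.0276054
905,0.0276103
906,0.0276151
907,0.0276198
908,0.0276244
909,0.0276289
910,0.0276333
911,0.0276376
912,0.0276418
913,0.0276459
914,0.0276499
915,0.0276538
916,0.0276576
917,0.0276613
918,0.0276649
919,0.0276684
920,0.0276718
921,0.027675
922,0.0276782
923,0.0276813
924,0.0276843
925,0.0276872
926,0.0276899
927,0.0276926
928,0.0276951
929,0.0276976
930,0.0276999
931,0.0277022
932,0.0277043
933,0.0277063
934,0.0277082
935,0.02771
936,0.0277117
937,0.0277132
938,0.0277147
939,0.027716
940,0.0277172
941,0.0277183
942,0.0277193
943,0.0277202
944,0.027721
945,0.0277216
946,0.0277222
947,0.0277226
948,0.0277229
949,0.0277231
950,0.0277231
951,0.0277195
952,0.0277088
953,0.0276915
954,0.027668
955,0.0276387
956,0.0276041
957,0.0275645
958,0.0275204
959,0.0274722
960,0.0274202
961,0.027365
962,0.0273069
963,0.0272464
964,0.0271838
965,0.0271196
966,0.0270541
967,0.0269879
968,0.0269214
969,0.0268548
970,0.0267887
971,0.0267235
972,0.0266596
973,0.0265974
974,0.0265373
975,0.0264797
976,0.0264232
977,0.026366
978,0.026308
979,0.0262493
980,0.0261899
981,0.0261298
982,0.026069
983,0.0260075
984,0.0259454
985,0.0258826
986,0.0258192
987,0.0257551
988,0.0256904
989,0.0256251
990,0.0255591
991,0.0254926
992,0.0254254
993,0.0253577
994,0.0252894
995,0.0252205
996,0.0251511
997,0.0250811
998,0.0250106
999,0.0249395
1000,0.0248679
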