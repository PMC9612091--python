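# Deoxyhemoglobin absorption coefficient, mm^-1 at 1 uM.
# Converted from molar extinction as ln(10)*eps*1e-6*0.1.
# SYNTHETIC fixture: monotone-cubic construction through anchor points
# at standard NIR absorption-feature positions; not a literature table.
# Generated by scripts/make_fixture_spectra.py.
wavelength_nm,value
650,0.0861858
651,0.0849747
652,0.0837759
653,0.0825895
654,0.0814156
655,0.0802541
656,0.0791052
657,0.0779688
658,0.0768451
659,0.075734
660,0.0746357
661,0.0735502
662,0.0724775
663,0.0714177
664,0.0703709
665,0.069337
666,0.0683162
667,0.0673085
668,0.0663139
669,0.0653325
670,0.0643644
671,0.0634096
672,0.0624681
673,0.06154
674,0.0606254
675,0.0597243
676,0.0588368
677,0.0579629
678,0.0571026
679,0.056256
680,0.0554232
681,0.054601
682,0.0537868
683,0.0529811
684,0.0521848
685,0.0513987
686,0.0506233
687,0.0498594
688,0.0491078
689,0.0483692
690,0.0476443
691,0.0469338
692,0.0462385
693,0.045559
694,0.0448962
695,0.0442507
696,0.0436232
697,0.0430145
698,0.0424253
699,0.0418564
700,0.0413084
701,0.040765
702,0.0402109
703,0.0396482
704,0.0390787
705,0.0385047
706,0.0379281
707,0.037351
708,0.0367754
709,0.0362034
710,0.0356371
711,0.0350784
712,0.0345295
713,0.0339923
714,0.0334689
715,0.0329614
716,0.0324718
717,0.0320022
718,0.0315546
719,0.031131
720,0.0307335
721,0.0303641
722,0.030025
723,0.0297181
724,0.0294454
725,0.0292091
726,0.0290112
727,0.0288537
728,0.0287386
729,0.0286681
730,0.0286442
731,0.0286567
732,0.0286935
733,0.0287537
734,0.0288362
735,0.02894
736,0.029064
737,0.0292073
738,0.0293687
739,0.0295473
740,0.029742
741,0.0299519
742,0.0301758
743,0.0304128
744,0.0306619
745,0.0309219
746,0.0311919
747,0.0314709
748,0.0317578
749,0.0320516
750,0.0323513
751,0.032767
752,0.0333728
753,0.0341137
754,0.0349344
755,0.0357801
756,0.0365955
757,0.0373256
758,0.0379153
759,0.0383095
760,0.0384532
761,0.0383804
762,0.0381706
763,0.0378362
764,0.0373898
765,0.0368438
766,0.0362109
767,0.0355036
768,0.0347343
769,0.0339157
770,0.0330602
771,0.0321804
772,0.0312888
773,0.030398
774,0.0295205
775,0.0286688
776,0.0278555
777,0.027093
778,0.026394
779,0.0257709
780,0.0252363
781,0.0247451
782,0.0242457
783,0.0237416
784,0.0232358
785,0.0227316
786,0.0222322
787,0.0217408
788,0.0212606
789,0.0207949
790,0.0203469
791,0.0199198
792,0.0195167
793,0.019141
794,0.0187958
795,0.0184843
796,0.0182098
797,0.0179755
798,0.0177845
799,0.0176402
800,0.0175457
801,0.017478
802,0.0174118
803,0.0173471
804,0.017284
805,0.0172224
806,0.0171623
807,0.0171038
808,0.0170467
809,0.0169912
810,0.0169371
811,0.0168845
812,0.0168334
813,0.0167838
814,0.0167356
815,0.0166889
816,0.0166437
817,0.0165998
818,0.0165574
819,0.0165164
820,0.0164769
821,0.0164387
822,0.016402
823,0.0163666
824,0.0163326
825,0.0163
826,0.0162688
827,0.0162389
828,0.0162104
829,0.0161832
830,0.0161574
831,0.0161329
832,0.0161098
833,0.0160879
834,0.0160674
835,0.0160481
836,0.0160302
837,0.0160135
838,0.0159982
839,0.0159841
840,0.0159712
841,0.0159597
842,0.0159493
843,0.0159403
844,0.0159324
845,0.0159258
846,0.0159204
847,0.0159162
848,0.0159132
849,0.0159115
850,0.0159109
851,0.0159119
852,0.0159151
853,0.0159202
854,0.0159272
855,0.015936
856,0.0159466
857,0.0159587
858,0.0159725
859,0.0159877
860,0.0160043
861,0.0160221
862,0.0160412
863,0.0160614
864,0.0160826
865,0.0161048
866,0.0161279
867,0.0161517
868,0.0161762
869,0.0162013
870,0.016227
871,0.016253
872,0.0162794
873,0.0163061
874,0.0163329
875,0.0163599
876,0.0163868
877,0.0164136
878,0.0164403
879,0.0164667
880,0.0164928
881,0.0165184
882,0.0165435
883,0.016568
884,0.0165919
885,0.0166149
886,0.0166371
887,0.0166583
888,0.0166785
889,0.0166976
890,0.0167155
891,0.0167321
892,0.0167473
893,0.016761
894,0.0167732
895,0.0167837
896,0.0167925
897,0.0167996
898,0.0168047
899,0.0168078
900,0.0168089
901,0.0168073
902,0.0168027
903,0.016795
904,0.0167845
905,0.0167713
906,0.0167554
907,0.0167369
908,0.0167159
909,0.0166926
910,0.016667
911,0.0166393
912,0.0166095
913,0.0165778
914,0.0165442
915,0.0165089
916,0.0164719
917,0.0164334
918,0.0163935
919,0.0163522
920,0.0163097
921,0.016266
922,0.0162213
923,0.0161757
924,0.0161293
925,0.0160821
926,0.0160343
927,0.015986
928,0.0159373
929,0.0158883
930,0.015839
931,0.0157897
932,0.0157403
933,0.015691
934,0.0156419
935,0.0155932
936,0.0155448
937,0.0154969
938,0.0154496
939,0.0154031
940,0.0153573
941,0.0153125
942,0.0152687
943,0.0152259
944,0.0151844
945,0.0151443
946,0.0151055
947,0.0150683
948,0.0150327
949,0.0149988
950,0.0149668
951,0.0149358
952,0.0149049
953,0.0148741
954,0.0148436
955,0.0148132
956,0.014783
957,0.0147531
958,0.0147234
959,0.0146939
960,0.0146648
961,0.014636
962,0.0146075
963,0.0145793
964,0.0145515
965,0.0145242
966,0.0144972
967,0.0144706
968,0.0144445
969,0.0144189
970,0.0143937
971,0.0143691
972,0.014345
973,0.0143214
974,0.0142984
975,0.014276
976,0.014254
977,0.0142323
978,0.0142107
979,0.0141895
980,0.0141685
981,0.0141477
982,0.0141272
983,0.014107
984,0.0140871
985,0.0140675
986,0.0140482
987,0.0140292
988,0.0140106
989,0.0139923
990,0.0139743
991,0.0139567
992,0.0139394
993,0.0139225
994,0.013906
995,0.0138899
996,0.0138742
997,0.0138589
998,0.013844
999,0.0138295
1000,0.0138155
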