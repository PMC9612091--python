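# Water absorption coefficient, mm^-1 at volume fraction 1.0.
# SYNTHETIC fixture: monotone-cubic construction through anchor points
# at standard NIR absorption-feature positions; not a literature table.
# Generated by scripts/make_fixture_spectra.py.
wavelength_nm,value
650,0.00032
651,0.000320139
652,0.000320555
653,0.000321243
654,0.000322201
655,0.000323425
656,0.000324912
657,0.000326659
658,0.000328662
659,0.000330917
660,0.000333423
661,0.000336174
662,0.000339168
663,0.000342402
664,0.000345873
665,0.000349576
666,0.000353508
667,0.000357667
668,0.000362049
669,0.00036665
670,0.000371468
671,0.000376498
672,0.000381738
673,0.000387184
674,0.000392833
675,0.000398682
676,0.000404727
677,0.000410964
678,0.000417392
679,0.000424005
680,0.000430802
681,0.000437777
682,0.00044493
683,0.000452255
684,0.000459749
685,0.00046741
686,0.000475234
687,0.000483217
688,0.000491356
689,0.000499648
690,0.00050809
691,0.000516678
692,0.000525409
693,0.00053428
694,0.000543286
695,0.000552426
696,0.000561695
697,0.00057109
698,0.000580608
699,0.000590246
700,0.0006
701,0.000610442
702,0.000622146
703,0.000635114
704,0.000649347
705,0.000664845
706,0.000681611
707,0.000699645
708,0.000718948
709,0.000739521
710,0.000761366
711,0.000784484
712,0.000808875
713,0.000834542
714,0.000861484
715,0.000889704
716,0.000919202
717,0.00094998
718,0.000982038
719,0.00101538
720,0.00105
721,0.00109364
722,0.00115277
723,0.00122546
724,0.0013098
725,0.00140387
726,0.00150576
727,0.00161355
728,0.00172532
729,0.00183916
730,0.00195316
731,0.00206539
732,0.00217395
733,0.00227691
734,0.00237235
735,0.00245837
736,0.00253305
737,0.00259447
738,0.00264071
739,0.00266986
740,0.00268
741,0.0026795
742,0.00267804
743,0.00267568
744,0.00267249
745,0.00266853
746,0.00266386
747,0.00265856
748,0.00265267
749,0.00264627
750,0.00263941
751,0.00263217
752,0.0026246
753,0.00261677
754,0.00260875
755,0.00260059
756,0.00259236
757,0.00258412
758,0.00257594
759,0.00256788
760,0.00256
761,0.00255188
762,0.0025431
763,0.0025337
764,0.00252377
765,0.00251334
766,0.0025025
767,0.00249129
768,0.00247977
769,0.00246802
770,0.00245608
771,0.00244402
772,0.00243189
773,0.00241977
774,0.00240771
775,0.00239577
776,0.00238401
777,0.00237249
778,0.00236128
779,0.00235043
780,0.00234
781,0.00232942
782,0.00231816
783,0.00230636
784,0.00229414
785,0.00228164
786,0.00226899
787,0.00225632
788,0.00224376
789,0.00223145
790,0.00221951
791,0.00220809
792,0.00219731
793,0.0021873
794,0.00217819
795,0.00217013
796,0.00216324
797,0.00215764
798,0.00215348
799,0.00215089
800,0.00215
801,0.00215274
802,0.00216073
803,0.0021736
804,0.00219102
805,0.00221263
806,0.00223807
807,0.002267
808,0.00229907
809,0.00233391
810,0.00237118
811,0.00241053
812,0.0024516
813,0.00249404
814,0.00253751
815,0.00258164
816,0.00262609
817,0.0026705
818,0.00271452
819,0.00275781
820,0.0028
821,0.00284349
822,0.00289068
823,0.00294118
824,0.00299463
825,0.00305066
826,0.00310891
827,0.003169
828,0.00323056
829,0.00329323
830,0.00335663
831,0.0034204
832,0.00348417
833,0.00354757
834,0.00361023
835,0.00367178
836,0.00373186
837,0.00379009
838,0.0038461
839,0.00389953
840,0.00395
841,0.00399838
842,0.00404581
843,0.00409233
844,0.00413802
845,0.00418292
846,0.00422709
847,0.00427058
848,0.00431346
849,0.00435577
850,0.00439758
851,0.00443893
852,0.00447989
853,0.00452051
854,0.00456084
855,0.00460095
856,0.00464088
857,0.0046807
858,0.00472045
859,0.0047602
860,0.0048
861,0.00483918
862,0.00487713
863,0.00491405
864,0.00495009
865,0.00498544
866,0.00502026
867,0.00505473
868,0.00508902
869,0.00512331
870,0.00515778
871,0.00519258
872,0.00522791
873,0.00526392
874,0.00530081
875,0.00533873
876,0.00537786
877,0.00541838
878,0.00546046
879,0.00550428
880,0.00555
881,0.00559662
882,0.00564319
883,0.00568999
884,0.00573729
885,0.00578539
886,0.00583455
887,0.00588504
888,0.00593716
889,0.00599118
890,0.00604737
891,0.00610601
892,0.00616738
893,0.00623176
894,0.00629943
895,0.00637066
896,0.00644573
897,0.00652493
898,0.00660852
899,0.00669678
900,0.00679
901,0.0068912
902,0.0070033
903,0.00712639
904,0.00726059
905,0.00740598
906,0.00756268
907,0.00773078
908,0.00791039
909,0.0081016
910,0.00830452
911,0.00851925
912,0.00874589
913,0.00898455
914,0.00923531
915,0.0094983
916,0.0097736
917,0.0100613
918,0.0103616
919,0.0106744
920,0.011
921,0.0113668
922,0.0118006
923,0.0122975
924,0.0128539
925,0.0134657
926,0.0141293
927,0.0148407
928,0.0155962
929,0.0163918
930,0.0172238
931,0.0180883
932,0.0189815
933,0.0198995
934,0.0208386
935,0.0217949
936,0.0227645
937,0.0237437
938,0.0247286
939,0.0257153
940,0.0267
941,0.0277676
942,0.0289787
943,0.0302929
944,0.0316701
945,0.0330699
946,0.0344521
947,0.0357765
948,0.0370028
949,0.0380907
950,0.039
951,0.0397815
952,0.0405149
953,0.0412031
954,0.041849
955,0.0424556
956,0.0430257
957,0.0435622
958,0.0440682
959,0.0445465
960,0.045
961,0.0454561
962,0.0459299
963,0.0464059
964,0.0468686
965,0.0473026
966,0.0476924
967,0.0480225
968,0.0482775
969,0.0484418
970,0.0485
971,0.0484823
972,0.0484314
973,0.0483502
974,0.0482421
975,0.04811
976,0.0479571
977,0.0477866
978,0.0476014
979,0.0474049
980,0.0472
981,0.0469349
982,0.046567
983,0.0461137
984,0.0455922
985,0.0450198
986,0.0444139
987,0.0437916
988,0.0431704
989,0.0425674
990,0.042
991,0.0414534
992,0.0409015
993,0.0403442
994,0.0397817
995,0.0392139
996,0.0386411
997,0.0380632
998,0.0374804
999,0.0368926
1000,0.0363
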