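# Lipid absorption coefficient, mm^-1 at volume fraction 1.0.
# SYNTHETIC fixture: monotone-cubic construction through anchor points
# at standard NIR absorption-feature positions; not a literature table.
# Generated by scripts/make_fixture_spectra.py.
wavelength_nm,value
650,0.0004
651,0.000400572
652,0.000401288
653,0.000402144
654,0.000403137
655,0.000404265
656,0.000405526
657,0.000406915
658,0.000408431
659,0.000410071
660,0.000411832
661,0.000413712
662,0.000415707
663,0.000417814
664,0.000420032
665,0.000422357
666,0.000424787
667,0.000427319
668,0.000429949
669,0.000432676
670,0.000435497
671,0.000438408
672,0.000441408
673,0.000444493
674,0.00044766
675,0.000450907
676,0.000454232
677,0.00045763
678,0.000461101
679,0.00046464
680,0.000468245
681,0.000471914
682,0.000475643
683,0.00047943
684,0.000483272
685,0.000487167
686,0.000491111
687,0.000495102
688,0.000499137
689,0.000503214
690,0.000507329
691,0.00051148
692,0.000515664
693,0.000519879
694,0.000524121
695,0.000528388
696,0.000532677
697,0.000536986
698,0.000541311
699,0.00054565
700,0.00055
701,0.000554481
702,0.000559208
703,0.000564175
704,0.000569374
705,0.000574798
706,0.00058044
707,0.000586293
708,0.000592348
709,0.0005986
710,0.00060504
711,0.000611662
712,0.000618458
713,0.000625421
714,0.000632544
715,0.000639819
716,0.000647239
717,0.000654797
718,0.000662485
719,0.000670298
720,0.000678226
721,0.000686263
722,0.000694402
723,0.000702635
724,0.000710955
725,0.000719355
726,0.000727827
727,0.000736365
728,0.000744961
729,0.000753608
730,0.000762298
731,0.000771025
732,0.000779781
733,0.000788558
734,0.00079735
735,0.000806149
736,0.000814948
737,0.00082374
738,0.000832518
739,0.000841273
740,0.00085
741,0.00085931
742,0.00086971
743,0.000881028
744,0.000893097
745,0.000905746
746,0.000918806
747,0.000932109
748,0.000945484
749,0.000958762
750,0.000971774
751,0.000984351
752,0.000996323
753,0.00100752
754,0.00101777
755,0.00102692
756,0.00103477
757,0.00104118
758,0.00104597
759,0.00104896
760,0.00105
761,0.00104839
762,0.00104375
763,0.00103641
764,0.00102667
765,0.00101484
766,0.00100125
767,0.000986198
768,0.00097
769,0.000952969
770,0.000935417
771,0.000917656
772,0.0009
773,0.00088276
774,0.00086625
775,0.000850781
776,0.000836667
777,0.000824219
778,0.00081375
779,0.000805573
780,0.0008
781,0.000795877
782,0.00079185
783,0.000787931
784,0.000784133
785,0.000780469
786,0.00077695
787,0.00077359
788,0.0007704
789,0.000767394
790,0.000764583
791,0.000761981
792,0.0007596
793,0.000757452
794,0.00075555
795,0.000753906
796,0.000752533
797,0.000751444
798,0.00075065
799,0.000750165
800,0.00075
801,0.00075064
802,0.000752523
803,0.0007556
804,0.000759817
805,0.000765123
806,0.000771467
807,0.000778795
808,0.000787057
809,0.0007962
810,0.000806173
811,0.000816923
812,0.0008284
813,0.000840551
814,0.000853323
815,0.000866667
816,0.000880528
817,0.000894857
818,0.0009096
819,0.000924706
820,0.000940123
821,0.0009558
822,0.000971684
823,0.000987723
824,0.00100387
825,0.00102006
826,0.00103626
827,0.0010524
828,0.00106844
829,0.00108432
830,0.0011
831,0.00111596
832,0.00113273
833,0.00115025
834,0.00116852
835,0.00118748
836,0.00120712
837,0.0012274
838,0.0012483
839,0.00126977
840,0.00129179
841,0.00131434
842,0.00133736
843,0.00136085
844,0.00138476
845,0.00140907
846,0.00143374
847,0.00145874
848,0.00148405
849,0.00150962
850,0.00153544
851,0.00156146
852,0.00158767
853,0.00161402
854,0.00164049
855,0.00166704
856,0.00169365
857,0.00172028
858,0.0017469
859,0.00177348
860,0.0018
861,0.00182617
862,0.00185183
863,0.00187713
864,0.00190224
865,0.00192729
866,0.00195244
867,0.00197785
868,0.00200365
869,0.00203002
870,0.00205709
871,0.00208501
872,0.00211395
873,0.00214405
874,0.00217546
875,0.00220834
876,0.00224283
877,0.00227909
878,0.00231727
879,0.00235753
880,0.0024
881,0.00244544
882,0.00249449
883,0.00254716
884,0.00260344
885,0.00266335
886,0.00272689
887,0.00279406
888,0.00286487
889,0.00293932
890,0.00301742
891,0.00309918
892,0.00318458
893,0.00327365
894,0.00336638
895,0.00346278
896,0.00356286
897,0.00366662
898,0.00377405
899,0.00388518
900,0.004
901,0.00412563
902,0.00426821
903,0.00442629
904,0.00459839
905,0.00478307
906,0.00497886
907,0.0051843
908,0.00539793
909,0.00561829
910,0.00584392
911,0.00607335
912,0.00630514
913,0.00653782
914,0.00676993
915,0.007
916,0.00725007
917,0.00753774
918,0.00785486
919,0.00819331
920,0.00854497
921,0.00890171
922,0.00925541
923,0.00959793
924,0.00992114
925,0.0102169
926,0.0104772
927,0.0106937
928,0.0108585
929,0.0109633
930,0.011
931,0.0109542
932,0.010824
933,0.0106206
934,0.0103551
935,0.0100385
936,0.00968185
937,0.00929631
938,0.00889292
939,0.00848277
940,0.00807692
941,0.00768646
942,0.00732246
943,0.006996
944,0.00671815
945,0.0065
946,0.00631586
947,0.00613352
948,0.00595423
949,0.00577926
950,0.00560987
951,0.00544732
952,0.00529286
953,0.00514776
954,0.00501328
955,0.00489068
956,0.00478123
957,0.00468617
958,0.00460677
959,0.00454429
960,0.0045
961,0.00446687
962,0.00443687
963,0.0044097
964,0.00438507
965,0.00436271
966,0.00434231
967,0.0043236
968,0.00430628
969,0.00429007
970,0.00427469
971,0.00425983
972,0.00424522
973,0.00423057
974,0.0042156
975,0.0042
976,0.00418351
977,0.00416625
978,0.00414848
979,0.0041305
980,0.00411259
981,0.00409504
982,0.00407813
983,0.00406214
984,0.00404736
985,0.00403407
986,0.00402257
987,0.00401312
988,0.00400602
989,0.00400155
990,0.004
991,0.00400414
992,0.00401605
993,0.00403498
994,0.00406016
995,0.00409083
996,0.00412624
997,0.00416562
998,0.00420821
999,0.00425326
1000,0.0043
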