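item_id,domain,difficulty
cognitive_01,cognitive,-6.844654459880793
cognitive_02,cognitive,-4.017712899265449
cognitive_03,cognitive,-3.303098640502901
cognitive_04,cognitive,-2.9723594427169013
cognitive_05,cognitive,-2.046395909787435
cognitive_06,cognitive,-0.7829845357904324
cognitive_07,cognitive,-0.5975897015514642
cognitive_08,cognitive,0.002944860708725905
cognitive_09,cognitive,3.2836400155657053
cognitive_10,cognitive,4.6120884907650765
cognitive_11,cognitive,5.377233411642498
language_01,language,-6.624376657781289
language_02,language,-4.567443922694351
language_03,language,-3.836698463689927
language_04,language,-0.6187229096779454
language_05,language,0.13684877783277027
language_06,language,0.5599723502256939
language_07,language,0.6216514083694387
language_08,language,3.905556843365206
language_09,language,4.846058123591289
language_10,language,5.681430628585771
language_11,language,5.899130070230935
language_12,language,7.429991817323739
language_13,language,7.584728409677828
gross_motor_01,gross_motor,-7.086154356373918
gross_motor_02,gross_motor,-5.620497798241671
gross_motor_03,gross_motor,-4.775454048364443
gross_motor_04,gross_motor,-4.7292975739421355
gross_motor_05,gross_motor,-4.118055333520897
gross_motor_06,gross_motor,-3.5496422088001314
gross_motor_07,gross_motor,-3.468706034504793
gross_motor_08,gross_motor,-3.3855734457548547
gross_motor_09,gross_motor,-0.9382230492822012
gross_motor_10,gross_motor,0.1988762501933996
gross_motor_11,gross_motor,1.925759161892886
gross_motor_12,gross_motor,2.1944225450704025
gross_motor_13,gross_motor,2.6776724190084185
gross_motor_14,gross_motor,3.1064801447080708
gross_motor_15,gross_motor,3.199786598703678
gross_motor_16,gross_motor,4.270304761017769
gross_motor_17,gross_motor,6.381176498268877
gross_motor_18,gross_motor,7.3625709755244735
gross_motor_19,gross_motor,7.642809524664468
fine_motor_01,fine_motor,-7.242676325215978
fine_motor_02,fine_motor,-6.270238018948679
fine_motor_03,fine_motor,-6.153041181769633
fine_motor_04,fine_motor,-5.7994624266657695
fine_motor_05,fine_motor,-5.5555597037670506
fine_motor_06,fine_motor,-5.1199043358820315
fine_motor_07,fine_motor,-4.623902708790863
fine_motor_08,fine_motor,-3.1467043654891818
fine_motor_09,fine_motor,-3.117178767314857
fine_motor_10,fine_motor,1.855281470552029
fine_motor_11,fine_motor,2.920843968379298
fine_motor_12,fine_motor,3.6009926576341336
fine_motor_13,fine_motor,4.841585516954719
fine_motor_14,fine_motor,5.064428020685961
fine_motor_15,fine_motor,5.11839889723322
fine_motor_16,fine_motor,6.525864373692777
fine_motor_17,fine_motor,7.189400176628769
fine_motor_18,fine_motor,7.871578047631523
social_01,social,-7.234900784208425
social_02,social,-6.915225462753673
social_03,social,-3.8183605845367796
social_04,social,-3.7999319924187875
social_05,social,-3.603161136746236
social_06,social,-2.5935235906450984
social_07,social,1.2318724670850134
social_08,social,2.4900902631167146
social_09,social,2.5071006522063257
social_10,social,3.137354500673734
social_11,social,3.2062550046958993
social_12,social,4.037913739099793
social_13,social,4.596483721526775
social_14,social,7.02056612577848
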