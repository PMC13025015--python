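name,analyte_class,units,internal_standard,lod,loq,cal_lower,cal_upper,ri_lower,ri_upper
3-Hydroxypropionic acid,organic_acid,umol_per_L,13C3_3-Hydroxypropionic acid,0.391,1.563,0.20,100,1.42,9.83
Methylcitric acid,organic_acid,umol_per_L,2H3_Methylcitric acid,0.024,0.098,0.20,50,0.10,0.38
Methylmalonic acid,organic_acid,umol_per_L,13C4_Methylmalonic acid,0.195,0.391,0.20,100,,0.37
Lactic acid,organic_acid,umol_per_L,13C3_Lactic acid,19.531,78.125,39.06,20000,1054.4,3902.9
Pyruvic acid,organic_acid,umol_per_L,13C3_Pyruvic acid,0.977,7.813,3.91,2000,45.4,248.4
3-Hydroxyisovaleric acid,organic_acid,umol_per_L,2H8_3-Hydroxyisovaleric acid,1.563,6.250,0.39,50,,7.03
Isovalerylglycine,organic_acid,umol_per_L,13C2_15N1_Isovalerylglycine,0.012,0.049,0.20,50,,0.01
3-Methylcrotonylglycine,organic_acid,umol_per_L,13C2_15N1_3-Methylcrotonylglycine,0.006,0.012,0.20,25,,0.01
3-Methylglutaric acid,organic_acid,au,,2000,,0.20,25,13931,57602
3-Methylglutaconic acid,organic_acid,au,,2000,,0.20,25,36298,131339
3-Hydroxy-3-methylglutaric acid,organic_acid,au,,2000,,0.20,25,108861,625203
3-Hydroxyglutaric acid,organic_acid,umol_per_L,2H5_3-Hydroxyglutaric acid,0.024,0.098,0.20,100,,0.45
2-Hydroxyglutaric acid,organic_acid,au,,2000,,0.20,50,130861,578833
Glutaric acid,organic_acid,umol_per_L,13C2_Glutaric acid,0.195,1.563,0.20,25,,2.10
2-Methyl-3-hydroxybutyric acid,organic_acid,au,,2000,,0.20,50,62577,333570
Tiglylglycine,organic_acid,au,,2000,,0.20,25,,2334
Orotic acid,organic_acid,au,,2000,,0.20,25,,3386
3-Hydroxybutyric acid,organic_acid,au,,2000,,0.98,125,866586,48966989
Adipic acid,organic_acid,au,,2000,,0.20,25,14869,165654
Suberic acid,organic_acid,au,,2000,,0.20,25,,590676
Sebacic acid,organic_acid,au,,2000,,0.20,25,,489304
Hexanoylglycine,organic_acid,au,,2000,,0.20,25,,2164
Suberylglycine,organic_acid,au,,2000,,0.20,25,,2011
Methylsuccinic acid,organic_acid,au,,2000,,0.20,25,23428,108437
Ethylmalonic acid,organic_acid,au,,2000,,0.20,25,44656,349780
Arginine,amino_acid,umol_per_L,13C6_Arginine,1.953,1.953,3.91,500,94.4,194.1
Glutamine,amino_acid,au,,2000,,3.91,1000,1417957,4570111
Citrulline,amino_acid,umol_per_L,2H7_Citrulline,0.031,0.122,1.95,500,18.9,50.3
Valine,amino_acid,umol_per_L,2H7_Valine,1.953,15.625,1.95,500,109.1,272.8
Tyrosine,amino_acid,umol_per_L,13C6_Tyrosine,0.488,1.953,1.95,500,56.6,160.8
Methionine,amino_acid,umol_per_L,2H3_Methionine,0.244,0.244,1.95,500,15.7,48.8
Leucine,amino_acid,umol_per_L,2H3_Leucine,7.813,31.250,1.95,500,99.6,246.5
Phenylalanine,amino_acid,umol_per_L,13C6_Phenylalanine,0.122,0.977,1.95,500,55.9,114.9
AC_C0,acylcarnitine,umol_per_L,2H9_AC_C0,0.0244,0.0488,0.20,100,13.37,28.83
AC_C2,acylcarnitine,umol_per_L,2H3_AC_C2,0.0031,0.0061,0.10,50,3.06,14.08
AC_C3,acylcarnitine,umol_per_L,2H3_AC_C3,0.0015,0.0015,0.02,12,0.160,0.615
AC_C4,acylcarnitine,umol_per_L,2H3_AC_C4,0.0024,0.0098,0.01,5,0.071,0.288
AC_C4DC,acylcarnitine,umol_per_L,2H9_AC_C5DC,0.0003,0.0006,0.01,5,0.017,0.051
AC_C5,acylcarnitine,umol_per_L,2H9_AC_C5,0.0002,0.0007,0.01,3,0.035,0.163
AC_C5:1,acylcarnitine,umol_per_L,2H9_AC_C5,0.0003,0.0003,0.01,5,0.002,0.015
AC_C5OH,acylcarnitine,umol_per_L,2H9_AC_C5OH,0.0006,0.0006,0.01,5,0.011,0.041
AC_C5DC,acylcarnitine,umol_per_L,2H9_AC_C5DC,0.0003,0.0006,0.00,2.5,0.008,0.028
AC_C6,acylcarnitine,umol_per_L,2H3_AC_C8,0.0003,0.0024,0.00,1.25,0.003,0.043
AC_C8,acylcarnitine,umol_per_L,2H3_AC_C8,0.0002,0.0003,0.00,2.5,0.014,0.167
AC_C10,acylcarnitine,umol_per_L,2H3_AC_C10,0.0003,0.0012,0.00,2.5,0.023,0.353
AC_C12,acylcarnitine,umol_per_L,2H3_AC_C12,0.0003,0.0012,0.00,2.5,0.007,0.110
AC_C14,acylcarnitine,umol_per_L,2H3_AC_C14,0.0007,0.0029,0.01,3,0.005,0.039
AC_C14:1,acylcarnitine,umol_per_L,2H3_AC_C14:1,0.0007,0.0029,0.01,3,0.008,0.130
AC_C16,acylcarnitine,umol_per_L,2H3_AC_C16,0.0059,0.0234,0.02,12,0.040,0.126
AC_C18,acylcarnitine,umol_per_L,2H3_AC_C18,0.0003,0.0195,0.01,5,0.011,0.038
AC_C16:1,acylcarnitine,au,,2000,,,,100743,723762
AC_C16OH,acylcarnitine,au,,2000,,,,20053,107215
AC_C18:1,acylcarnitine,au,,2000,,,,1189675,4733385
AC_C18:1OH,acylcarnitine,au,,2000,,,,18202,209737
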