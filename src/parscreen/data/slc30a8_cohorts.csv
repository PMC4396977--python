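cohort_id,group,n_cases,cc_cases,raf_cases,n_controls,cc_controls,raf_controls,cc_source_cases,cc_source_controls
Horikoshi,asian,860,328,0.604,859,293,0.57,reported,reported
Steinsthosdottir,asian,1426,464,0.566,970,259,0.523,reported,reported
Furukawa,asian,405,151,0.616,340,121,0.593,reported,reported
Horikawa,asian,1830,690,0.6,1574,522,0.56,reported,reported
Lee,asian,908,324,0.61,502,156,0.558,reported,reported
Omori,asian,1614,651,0.633,1045,381,0.6,reported,reported
Sanghera,asian,532,290,0.728,349,188,0.732,reported,reported
Hu,asian,1849,695,0.613,1785,558,0.559,hwe_derived,hwe_derived
Tabara,asian,493,162,0.591,400,133,0.568,reported,reported
Chauhan,asian,2466,1578,0.8,2539,1505,0.77,hwe_derived,hwe_derived
Han,asian,992,386,0.62,1005,327,0.57,reported,reported
Huang,asian,443,134,0.541,229,64,0.483,reported,reported
Lin,asian,1529,532,0.59,1439,420,0.54,hwe_derived,hwe_derived
Ng-1,asian,1481,485,0.572,1530,433,0.532,hwe_derived,hwe_derived
Ng-2,asian,761,299,0.627,632,216,0.585,hwe_derived,hwe_derived
Ng-3,asian,799,278,0.59,1516,514,0.582,hwe_derived,hwe_derived
Wu,asian,424,144,0.583,2786,899,0.568,hwe_derived,hwe_derived
Xiang,asian,521,175,0.579,721,203,0.53,hwe_derived,hwe_derived
Tan-1,asian,1541,433,0.53,2196,617,0.53,hwe_derived,hwe_derived
Tan-2,asian,1076,375,0.59,2257,733,0.57,hwe_derived,hwe_derived
Tan-3,asian,246,146,0.77,364,199,0.74,hwe_derived,hwe_derived
Scott,european,2342,1011,0.649,2397,891,0.609,reported,reported
Sladek,european,2562,1440,0.746,2878,1413,0.699,reported,reported
Steinthorsdottir,european,3776,1871,0.7,12361,5575,0.666,reported,reported
Zeggini,european,1550,794,0.712,2866,1393,0.694,reported,reported
Cauchi-1,european,2715,1453,0.729,4255,2114,0.705,reported,reported
Cauchi-2,european,828,360,0.74,952,367,0.699,reported,reported
Cauchi-3,european,437,240,0.653,676,331,0.626,reported,reported
Gamboa-Melendez,mexican,1027,609,0.77,990,526,0.729,reported,reported
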