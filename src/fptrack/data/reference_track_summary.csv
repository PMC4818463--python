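transmitter,species,site,start,end,nd_days,tf_fixes,fd,ns_segments,uds_count,uda_mean_km2,uda_sd_km2,udd_mean_days,udd_sd_days
77092,RBT,STR,2008-03-12,2009-03-26,379,1804,4.8,5,31,2.24,2.42,15.8,23
77093,RBT,STR,2008-03-12,2008-09-07,179,993,5.5,3,12,1.95,1.24,22.1,20.7
77098,RBT,STR,2008-03-14,2009-11-24,620,3550,5.7,5,44,2.26,2.18,20.6,30.8
77099,RBT,STR,2008-03-14,2009-05-15,427,1859,4.4,4,23,3.41,3.27,20.8,25.2
77100,RBT,STR,2008-03-14,2009-04-16,398,2046,5.1,6,42,1.95,1.32,14.5,16.9
77101,RBT,BAR,2008-04-09,2008-09-28,172,740,4.3,3,11,3.42,2.19,22.2,22.6
77102,RBT,BAR,2008-04-10,2010-04-20,740,4155,5.6,4,82,1.54,0.98,13.5,24
77103,RBT,MAN,2008-05-05,2008-08-24,111,610,5.5,3,33,2.57,2.73,6,7.6
77104,RBT,MAN,2008-05-05,2009-01-25,265,1431,5.4,3,43,1.79,1.74,10.3,21.3
77106,RBT,MAN,2008-05-06,2009-07-25,445,2587,5.8,7,34,2.3,2.09,19.4,25.2
77108,RBT,MAN,2008-05-06,2008-08-29,115,644,5.6,4,22,2.67,3.1,10.5,11.9
77109,RBT,MAN,2008-05-07,2008-12-24,231,1307,5.7,4,37,1.88,1.12,12.3,23.2
77112,RBT,BAR,2008-06-07,2009-05-15,342,1843,5.4,3,23,2.15,2.49,21.8,43.6
77115,RBT,BAR,2008-10-11,2009-07-15,277,1429,5.2,4,20,2.16,1.37,11.6,15
77094,EG,STR,2008-01-12,2008-05-09,118,1218,10.3,4,15,1.99,1.14,12.1,9.6
77094a,EG,STR,2008-08-20,2009-05-01,254,2686,10.6,3,9,2.59,2.29,21.2,34.3
77095,EG,STR,2008-01-12,2009-01-03,357,3397,9.5,5,32,2.29,1.93,15.5,22.3
7711702,EG,JOZ,2012-05-04,2012-09-20,139,1669,12.0,5,13,2.25,1.24,13.3,13.9
7711802,EG,STR,2009-01-17,2010-10-11,632,6453,10.2,5,58,2.56,2.93,18.1,31.3
7712002,EG,JOZ,2012-05-04,2013-05-24,385,4317,11.2,2,86,3.12,3.06,11.5,17.7
7712002a,EG,JOZ,2013-06-09,2014-01-31,236,2592,11.0,3,43,1.93,1.6,10.9,15.9
7712102,EG,JOZ,2012-05-05,2012-09-03,121,1309,10.8,3,4,2.21,1.19,30.5,19.8
7712202,EG,BAR,2008-10-23,2009-05-30,219,2123,9.7,5,37,1.87,1.7,8.5,13.4
7712302,EG,STR,2008-12-05,2009-06-02,179,1756,9.8,4,7,2.53,1.26,23.9,30.7
77125,EG,MAN,2008-05-07,2010-02-21,655,6965,10.6,5,120,2.29,2.98,11.6,24.1
77125a,EG,MAN,2010-04-17,2011-05-31,409,3689,9.0,3,60,2.68,2.76,15.6,21.4
77126,EG,MAN,2008-05-07,2008-12-26,233,2682,11.5,5,29,2.33,2.86,12.6,16.5
77127,EG,BAR,2008-06-07,2010-05-10,702,6351,9.0,6,54,2.7,3.32,17.3,26.9
77128,EG,BAR,2008-06-22,2009-06-06,349,3551,10.2,3,31,1.81,1.9,10.4,25.4
77128a,EG,BAR,2009-08-15,2010-05-25,283,2551,9.0,3,64,1.81,1.9,6.5,14.3
77128b,EG,BAR,2010-09-25,2011-05-06,223,1998,9.0,3,28,1.67,0.96,5.7,12.1
77128c,EG,BAR,2011-07-31,2011-12-02,124,653,5.3,4,16,2.09,1.4,8.8,11.5
77129,EG,BAR,2008-06-07,2009-05-15,342,3491,10.2,5,61,2.13,1.73,9.6,17.5
77130,EG,BAR,2008-11-09,2009-09-19,314,2489,7.9,5,76,2.2,1.76,8.6,12.6
77130a,EG,BAR,2009-10-04,2010-06-04,243,2140,8.8,5,78,1.86,1.5,6.5,10.8
77132,EG,BAR,2008-06-07,2009-05-30,357,2601,7.3,3,35,2.01,1.94,15.5,25.4
77132a,EG,BAR,2009-08-13,2010-04-14,244,2090,8.6,2,12,2.15,0.46,14.8,27.3
7713301,EG,STR,2008-12-04,2009-04-27,144,1506,10.5,5,40,1.83,1.2,4,5.1
7713302,EG,JOZ,2012-05-04,2013-02-19,291,3009,10.3,3,27,2.81,2.17,15.7,23
77134,EG,STR,2008-12-01,2010-07-29,605,5330,8.8,4,19,3.28,2.47,24.2,28.8
77134a,EG,STR,2010-08-19,2011-05-02,256,2561,10.0,5,17,2.04,2.16,19.2,29.9
77134b,EG,STR,2011-07-22,2012-04-12,265,2401,9.1,3,8,2.08,1.66,47.1,46.2
77135,EG,STR,2008-12-01,2011-02-08,799,8522,10.7,4,107,2.5,2.82,11.5,18
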