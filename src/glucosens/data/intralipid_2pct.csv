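wavelength_nm,layer,mu_a_mm-1,mu_s_mm-1,g,n
1000.0,intralipid_2pct,0.04,2.088987,0.52,1.33
1010.0,intralipid_2pct,0.036,2.01534,0.5142,1.33
1020.0,intralipid_2pct,0.032,1.945023,0.5084,1.33
1030.0,intralipid_2pct,0.028,1.877854,0.5026,1.33
1040.0,intralipid_2pct,0.024,1.813662,0.4968,1.33
1050.0,intralipid_2pct,0.02,1.752286,0.491,1.33
1060.0,intralipid_2pct,0.0194,1.693575,0.4852,1.33
1070.0,intralipid_2pct,0.0188,1.637389,0.4794,1.33
1080.0,intralipid_2pct,0.0182,1.583595,0.4736,1.33
1090.0,intralipid_2pct,0.0176,1.53207,0.4678,1.33
1100.0,intralipid_2pct,0.017,1.482697,0.462,1.33
1110.0,intralipid_2pct,0.0256,1.435366,0.4562,1.33
1120.0,intralipid_2pct,0.0342,1.389975,0.4504,1.33
1130.0,intralipid_2pct,0.0428,1.346427,0.4446,1.33
1140.0,intralipid_2pct,0.0514,1.304631,0.4388,1.33
1150.0,intralipid_2pct,0.06,1.264501,0.433,1.33
1160.0,intralipid_2pct,0.069,1.225956,0.4272,1.33
1170.0,intralipid_2pct,0.078,1.18892,0.4214,1.33
1180.0,intralipid_2pct,0.087,1.15332,0.4156,1.33
1190.0,intralipid_2pct,0.096,1.11909,0.4098,1.33
1200.0,intralipid_2pct,0.105,1.086165,0.404,1.33
1210.0,intralipid_2pct,0.102,1.054484,0.3982,1.33
1220.0,intralipid_2pct,0.099,1.02399,0.3924,1.33
1230.0,intralipid_2pct,0.096,0.994629,0.3866,1.33
1240.0,intralipid_2pct,0.093,0.966349,0.3808,1.33
1250.0,intralipid_2pct,0.09,0.939102,0.375,1.33
1260.0,intralipid_2pct,0.096,0.912843,0.3692,1.33
1270.0,intralipid_2pct,0.102,0.887527,0.3634,1.33
1280.0,intralipid_2pct,0.108,0.863113,0.3576,1.33
1290.0,intralipid_2pct,0.114,0.839562,0.3518,1.33
1300.0,intralipid_2pct,0.12,0.816837,0.346,1.33
1310.0,intralipid_2pct,0.146,0.794902,0.3402,1.33
1320.0,intralipid_2pct,0.172,0.773724,0.3344,1.33
1330.0,intralipid_2pct,0.198,0.753272,0.3286,1.33
1340.0,intralipid_2pct,0.224,0.733514,0.3228,1.33
1350.0,intralipid_2pct,0.25,0.714423,0.317,1.33
1360.0,intralipid_2pct,0.44,0.69597,0.3112,1.33
1370.0,intralipid_2pct,0.63,0.67813,0.3054,1.33
1380.0,intralipid_2pct,0.82,0.660878,0.2996,1.33
1390.0,intralipid_2pct,1.01,0.64419,0.2938,1.33
1400.0,intralipid_2pct,1.2,0.628044,0.288,1.33
1410.0,intralipid_2pct,1.54,0.612418,0.2822,1.33
1420.0,intralipid_2pct,1.88,0.597292,0.2764,1.33
1430.0,intralipid_2pct,2.22,0.582646,0.2706,1.33
1440.0,intralipid_2pct,2.56,0.568462,0.2648,1.33
1450.0,intralipid_2pct,2.9,0.554722,0.259,1.33
1460.0,intralipid_2pct,2.74,0.541409,0.2532,1.33
1470.0,intralipid_2pct,2.58,0.528508,0.2474,1.33
1480.0,intralipid_2pct,2.42,0.516001,0.2416,1.33
1490.0,intralipid_2pct,2.26,0.503875,0.2358,1.33
1500.0,intralipid_2pct,2.1,0.492116,0.23,1.33
1510.0,intralipid_2pct,1.89,0.480709,0.2242,1.33
1520.0,intralipid_2pct,1.68,0.469643,0.2184,1.33
1530.0,intralipid_2pct,1.47,0.458904,0.2126,1.33
1540.0,intralipid_2pct,1.26,0.448482,0.2068,1.33
1550.0,intralipid_2pct,1.05,0.438363,0.201,1.33
1560.0,intralipid_2pct,0.97,0.428539,0.1952,1.33
1570.0,intralipid_2pct,0.89,0.418997,0.1894,1.33
1580.0,intralipid_2pct,0.81,0.409729,0.1836,1.33
1590.0,intralipid_2pct,0.73,0.400725,0.1778,1.33
1600.0,intralipid_2pct,0.65,0.391975,0.172,1.33
1610.0,intralipid_2pct,0.62,0.383471,0.1662,1.33
1620.0,intralipid_2pct,0.59,0.375205,0.1604,1.33
1630.0,intralipid_2pct,0.56,0.367168,0.1546,1.33
1640.0,intralipid_2pct,0.53,0.359352,0.1488,1.33
1650.0,intralipid_2pct,0.5,0.351751,0.143,1.33
1660.0,intralipid_2pct,0.51,0.344356,0.1372,1.33
1670.0,intralipid_2pct,0.52,0.337161,0.1314,1.33
1680.0,intralipid_2pct,0.53,0.33016,0.1256,1.33
1690.0,intralipid_2pct,0.54,0.323346,0.1198,1.33
1700.0,intralipid_2pct,0.55,0.316713,0.114,1.33
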