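wavelength_nm,dmua_dCg_mm-1_per_mmolL
1000.0,1e-06
1010.0,1.1e-06
1020.0,1.2e-06
1030.0,1.3e-06
1040.0,1.4e-06
1050.0,1.5e-06
1060.0,1.6e-06
1070.0,1.7e-06
1080.0,1.8e-06
1090.0,1.9e-06
1100.0,2e-06
1110.0,2.3e-06
1120.0,2.6e-06
1130.0,2.9e-06
1140.0,3.2e-06
1150.0,3.5e-06
1160.0,3.8e-06
1170.0,4.1e-06
1180.0,4.4e-06
1190.0,4.7e-06
1200.0,5e-06
1210.0,5.3e-06
1220.0,5.6e-06
1230.0,5.9e-06
1240.0,6.2e-06
1250.0,6.5e-06
1260.0,6.8e-06
1270.0,7.1e-06
1280.0,7.4e-06
1290.0,7.7e-06
1300.0,8e-06
1310.0,9.4e-06
1320.0,1.08e-05
1330.0,1.22e-05
1340.0,1.36e-05
1350.0,1.5e-05
1360.0,2e-05
1370.0,2.5e-05
1380.0,3e-05
1390.0,3.5e-05
1400.0,4e-05
1410.0,4.4e-05
1420.0,4.8e-05
1430.0,5.2e-05
1440.0,5.6e-05
1450.0,6e-05
1460.0,6.4e-05
1470.0,6.8e-05
1480.0,7.2e-05
1490.0,7.6e-05
1500.0,8e-05
1510.0,8.4e-05
1520.0,8.8e-05
1530.0,9.2e-05
1540.0,9.6e-05
1550.0,0.0001
1560.0,0.000104
1570.0,0.000108
1580.0,0.000112
1590.0,0.000116
1600.0,0.00012
1610.0,0.000116
1620.0,0.000112
1630.0,0.000108
1640.0,0.000104
1650.0,0.0001
1660.0,9.8e-05
1670.0,9.6e-05
1680.0,9.4e-05
1690.0,9.2e-05
1700.0,9e-05
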