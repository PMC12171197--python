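method,wavelength_nm
SPA,935.61
SPA,939.06
SPA,945.98
SPA,970.19
SPA,1206.87
SPA,1322.66
SPA,1364.92
SPA,1393.14
SPA,1410.79
SPA,1428.46
SPA,1453.22
SPA,1520.56
SPA,1584.55
SPA,1670.14
SPA,1688.02
SPA,1702.33
SPA,1709.49
SPA,1720.23
UVE,935.61
UVE,939.06
UVE,942.52
UVE,945.98
UVE,1375.50
UVE,1379.02
UVE,1382.55
UVE,1386.08
UVE,1389.61
UVE,1393.14
UVE,1428.46
UVE,1431.99
UVE,1435.53
UVE,1439.07
UVE,1442.60
UVE,1446.14
UVE,1513.46
UVE,1517.01
UVE,1520.56
UVE,1524.11
UVE,1527.66
UVE,1670.14
UVE,1673.72
CARS,945.98
CARS,1238.39
CARS,1308.59
CARS,1357.87
CARS,1364.92
CARS,1393.14
CARS,1421.39
CARS,1499.27
CARS,1577.43
CARS,1652.29
CARS,1688.02
CARS,1716.65
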