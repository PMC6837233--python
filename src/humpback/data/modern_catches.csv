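year,core,falkland,fringe,overlap
1904,180,0,180,144
1905,288,0,288,233
1906,240,0,240,242
1907,1261,0,1261,1045
1908,1849,6,1849,1605
1909,3391,66,3391,2870
1910,6468,49,6468,5434
1911,5832,12,5832,4892
1912,2881,6,2881,2472
1913,999,5,999,974
1914,1155,8,1155,1054
1915,1697,0,1697,1396
1916,447,0,447,373
1917,121,0,121,116
1918,129,0,129,124
1919,111,0,111,113
1920,102,0,102,97
1921,9,0,9,7
1922,364,0,364,310
1923,133,0,133,116
1924,266,0,266,223
1925,254,0,254,220
1926,7,0,7,16
1927,0,1,0,0
1928,19,0,19,17
1929,51,0,56,42
1930,107,0,120,92
1931,18,0,19,15
1932,23,0,24,20
1933,132,0,151,114
1934,57,0,64,49
1935,48,0,149,68
1936,105,0,149,109
1937,242,0,275,213
1938,0,0,0,0
1939,2,0,2,2
1940,36,0,92,53
1941,13,0,13,10
1942,0,0,0,0
1943,4,0,4,3
1944,60,0,60,48
1945,238,0,238,190
1946,30,0,31,24
1947,35,0,36,30
1948,48,0,67,51
1949,83,0,212,116
1950,698,0,712,614
1951,45,0,102.5,84
1952,34,0,50.5,49
1953,140,0,155.5,124
1954,44,0,70,71
1955,96,0,137.5,94
1956,167,0,199.5,210
1957,61,2,77.5,61
1958,16,0,19,28
1959,15,37,15,39
1960,27,0,29,45
1961,13,4,13,132
1962,24,1,26,53
1963,12,22,12,12
1964,0,0,0,0
1965,52,0,69,133
1966,0,0,0,15
1967,189,0,192,226
1968,0,0,0,0
1969,0,0,0,0
1970,0,0,0,0
1971,0,0,0,0
1972,2,0,2,2
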