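start_year,end_year,brazil_min,brazil_max,pelagic
1830,1839,1200,4000,0
1840,1849,1200,4000,28
1850,1859,1200,4000,0
1860,1869,1200,4000,181
1870,1879,1200,4000,0
1880,1889,1200,4000,0
1890,1893,480,1600,0
1894,1894,120,400,48
1895,1900,720,2400,0
1901,1902,543,1163,0
1903,1903,120,400,0
1904,1905,543,1163,0
1906,1907,240,800,0
1908,1908,459,807,0
1909,1909,310,628,0
1910,1910,326,647,0
1911,1924,420,700,0
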