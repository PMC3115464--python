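year,index
1990,162.8
1991,177.0
1992,190.1
1993,201.4
1994,211.0
1995,220.5
1996,228.2
1997,234.6
1998,242.1
1999,250.6
2000,260.8
2001,272.8
2002,285.6
2003,297.1
2004,310.1
2005,323.2
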