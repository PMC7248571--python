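year,index,currency,fx_rate
1990,0.597579,USD,1.0
1990,0.597579,EUR,1.11
1990,0.597579,GBP,1.35
1991,0.609531,USD,1.0
1991,0.609531,EUR,1.11
1991,0.609531,GBP,1.35
1992,0.621721,USD,1.0
1992,0.621721,EUR,1.11
1992,0.621721,GBP,1.35
1993,0.634156,USD,1.0
1993,0.634156,EUR,1.11
1993,0.634156,GBP,1.35
1994,0.646839,USD,1.0
1994,0.646839,EUR,1.11
1994,0.646839,GBP,1.35
1995,0.659776,USD,1.0
1995,0.659776,EUR,1.11
1995,0.659776,GBP,1.35
1996,0.672971,USD,1.0
1996,0.672971,EUR,1.11
1996,0.672971,GBP,1.35
1997,0.686431,USD,1.0
1997,0.686431,EUR,1.11
1997,0.686431,GBP,1.35
1998,0.700159,USD,1.0
1998,0.700159,EUR,1.11
1998,0.700159,GBP,1.35
1999,0.714163,USD,1.0
1999,0.714163,EUR,1.11
1999,0.714163,GBP,1.35
2000,0.728446,USD,1.0
2000,0.728446,EUR,1.11
2000,0.728446,GBP,1.35
2001,0.743015,USD,1.0
2001,0.743015,EUR,1.11
2001,0.743015,GBP,1.35
2002,0.757875,USD,1.0
2002,0.757875,EUR,1.11
2002,0.757875,GBP,1.35
2003,0.773033,USD,1.0
2003,0.773033,EUR,1.11
2003,0.773033,GBP,1.35
2004,0.788493,USD,1.0
2004,0.788493,EUR,1.11
2004,0.788493,GBP,1.35
2005,0.804263,USD,1.0
2005,0.804263,EUR,1.11
2005,0.804263,GBP,1.35
2006,0.820348,USD,1.0
2006,0.820348,EUR,1.11
2006,0.820348,GBP,1.35
2007,0.836755,USD,1.0
2007,0.836755,EUR,1.11
2007,0.836755,GBP,1.35
2008,0.853490,USD,1.0
2008,0.853490,EUR,1.11
2008,0.853490,GBP,1.35
2009,0.870560,USD,1.0
2009,0.870560,EUR,1.11
2009,0.870560,GBP,1.35
2010,0.887971,USD,1.0
2010,0.887971,EUR,1.11
2010,0.887971,GBP,1.35
2011,0.905731,USD,1.0
2011,0.905731,EUR,1.11
2011,0.905731,GBP,1.35
2012,0.923845,USD,1.0
2012,0.923845,EUR,1.11
2012,0.923845,GBP,1.35
2013,0.942322,USD,1.0
2013,0.942322,EUR,1.11
2013,0.942322,GBP,1.35
2014,0.961169,USD,1.0
2014,0.961169,EUR,1.11
2014,0.961169,GBP,1.35
2015,0.980392,USD,1.0
2015,0.980392,EUR,1.11
2015,0.980392,GBP,1.35
2016,1.000000,USD,1.0
2016,1.000000,EUR,1.11
2016,1.000000,GBP,1.35
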