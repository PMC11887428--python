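# Computed CCS for glycan charge-model candidates AFTER conformational
# sampling against experimental DTIMS references. calc_A2 and the
# parenthetical percent errors are stored verbatim as printed; empty cells
# mean no experimental value. The Mannohexaose stepped_err as printed
# (14.52) does not recompute from its CCS columns (10.32 does); the row is
# flagged printed_inconsistent=1 and stored verbatim.
index,analyte,mode,calc_A2,single_A2,single_err,stepped_A2,stepped_err,avg_A2,avg_err,printed_inconsistent
1,Cellobiose,neg,174.33,179.70,2.99,167.86,3.85,173.78,0.32,0
2,Glucuronate,neg,128,131.70,2.50,134.23,4.34,132.97,3.43,0
3,Inositol,neg,130,129.95,0.14,144.27,10.05,137.11,5.36,0
4,Isomaltose,neg,170,171.96,1.10,180.77,5.92,176.37,3.57,0
5,Isomaltotriose,neg,207.99,,,202.92,2.50,202.92,2.50,0
6,Lacto-N-Fucopentaose I,neg,295.35,,,275.87,7.06,275.87,7.06,0
7,Lacto-N-Neotetraose,neg,251.96,,,254.73,1.09,254.73,1.09,0
8,Lactose,neg,172,176.90,3.05,170.23,0.75,173.57,1.18,0
9,Lactulose,neg,176.12,,,178.23,1.18,178.23,1.18,0
10,Maltose,neg,175.19,180.10,2.73,205.90,14.92,193.00,9.23,0
11,Maltotetraose,neg,253.18,,,221.08,14.52,221.08,14.52,0
12,Mannitol,neg,127.93,131.60,2.79,,,131.60,2.79,0
13,Mannohexaose,neg,305.88,,,277.27,14.52,277.27,10.32,1
14,Mannotetraose,neg,238.53,,,223.26,6.84,223.26,6.84,0
15,Melezitose,neg,201.76,,,203.52,0.86,203.52,0.86,0
16,Melibiose,neg,165,178.10,7.48,172.63,4.55,175.36,6.04,0
17,Palatinose,neg,171,177.90,3.74,172.60,0.79,175.25,2.29,0
18,Raffinose,neg,198.7,197.30,0.68,197.59,0.54,197.45,0.61,0
19,Sorbitol,neg,124.41,130.52,4.68,,,130.52,4.68,0
20,Sucrose,neg,171,168.20,1.49,168.47,1.33,168.34,1.41,0
21,Tagatose,neg,126.15,129.77,2.79,,,129.77,2.79,0
22,Xylitol,neg,121,124.33,2.48,127.92,5.21,126.13,3.87,0
23,Xylobiose,neg,166.75,,,166.93,0.11,166.93,0.11,0
24,Glucosamine,pos,129,139.75,7.50,135.59,4.66,137.67,6.10,0
25,Maltotetraose,pos,236.51,,,238.30,0.75,238.30,0.75,0
26,Melezitose,pos,200.53,,,202.60,1.02,202.60,1.02,0
27,Sorbitol,pos,128.66,,,147.20,12.60,147.20,12.60,0
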