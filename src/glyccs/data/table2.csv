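# Computed CCS for glycan charge-model candidates BEFORE conformational
# sampling ("fast" approach) against experimental DTIMS references.
# calc_A2 and the parenthetical percent errors are stored verbatim as
# printed; empty cells mean no experimental value available.
index,analyte,mode,calc_A2,single_A2,single_err,stepped_A2,stepped_err,avg_A2,avg_err,printed_inconsistent
1,Cellobiose,neg,170,179.70,5.38,167.86,1.29,173.78,2.16,0
2,Glucuronate,neg,134,131.70,1.53,134.23,0.38,132.97,0.57,0
3,Inositol,neg,130,129.95,0.03,144.27,9.95,137.11,5.25,0
4,Isomaltose,neg,164.49,171.96,4.34,180.77,9.01,176.37,6.73,0
5,Isomaltotriose,neg,197.44,,,202.92,2.70,202.92,2.70,0
6,Lacto-N-Fucopentaose I,neg,312.79,,,275.87,13.38,275.87,13.38,0
7,Lacto-N-Neotetraose,neg,277.59,,,254.73,8.97,254.73,8.97,0
8,Lactose,neg,173.41,176.90,1.97,170.23,1.87,173.57,0.09,0
9,Lactulose,neg,173.30,,,178.23,2.77,178.23,2.77,0
10,Maltose,neg,173,180.10,4.19,205.90,16.20,193.00,10.60,0
11,Maltotetraose,neg,254.38,,,221.08,15.06,221.08,15.06,0
12,Mannitol,neg,127.44,131.60,3.16,,,131.60,3.16,0
13,Mannohexaose,neg,363.03,,,277.27,30.93,277.27,30.93,0
14,Mannotetraose,neg,259.88,,,223.26,16.40,223.26,16.40,0
15,Melezitose,neg,205.21,,,203.52,0.83,203.52,0.83,0
16,Melibiose,neg,173,178.10,2.93,172.63,0.14,175.36,1.42,0
17,Palatinose,neg,168,177.90,5.76,172.60,2.87,175.25,4.34,0
18,Raffinose,neg,209,197.30,6.00,197.59,5.85,197.45,5.92,0
19,Sorbitol,neg,133.72,130.52,2.45,,,130.52,2.45,0
20,Sucrose,neg,167.8,168.20,0.24,168.47,0.40,168.34,0.32,0
21,Tagatose,neg,127.00,129.77,2.13,,,129.77,2.13,0
22,Xylitol,neg,124,124.33,0.76,127.92,3.54,126.13,2.17,0
23,Xylobiose,neg,167.29,,,166.93,0.22,166.93,0.22,0
24,Glucosamine,pos,131,139.75,6.52,135.59,3.65,137.67,5.11,0
25,Maltotetraose,pos,228.95,,,238.30,3.92,238.30,3.92,0
26,Melezitose,pos,190.63,,,202.60,5.91,202.60,5.91,0
27,Sorbitol,pos,129.83,,,147.20,11.80,147.20,11.80,0
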