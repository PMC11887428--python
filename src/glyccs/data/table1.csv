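# Experimental DTIMS reference CCS (N2) for glycans: stepped-field vs
# calibrated single-field protocols, as printed in the source reference
# tables bundled with this package. Units: Angstrom^2.
analyte,mode,stepped_A2,single_A2,abs_delta_printed,pct_delta_printed
Cellobiose,neg,167.86,179.70,11.84,6.81
Glucosamine,pos,135.59,139.75,4.16,3.02
Glucuronate,neg,134.23,131.70,2.53,1.90
Inositol,neg,144.27,129.96,14.32,10.44
Isomaltose,neg,180.77,171.96,8.81,5.00
Lactose,neg,170.23,176.90,6.67,3.84
Maltose,neg,205.90,180.10,25.80,13.37
Palatinose,neg,172.60,177.90,5.30,3.02
Raffinose,neg,197.59,197.30,0.29,0.15
Stachyose,neg,226.67,222.61,4.06,1.81
Sucrose,neg,168.47,168.20,0.27,0.16
Xylitol,neg,127.92,124.1,3.82,3.03
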