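# Observed LC-MS peaks from a digested-nucleotide / nucleoside analysis of
# hypermodified phage DNA.  Nucleotide peaks (negative mode, 2-decimal
# precision) carry the coarse tolerance; 4-decimal peaks the fine one.
# The 360.10 row is an MRM precursor-isolation setpoint, printed to two
# decimals, so it carries an isolation-window tolerance rather than a
# calibrated-centroid tolerance.
mz,adduct,tol
321.06,[M-H]-,0.03
330.07,[M-H]-,0.03
346.08,[M-H]-,0.03
438.094,[M-H]-,0.005
535.0360,[M-H]-,0.005
360.10,[M+H]+,0.05
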