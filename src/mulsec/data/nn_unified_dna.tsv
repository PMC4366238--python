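# Unified nearest-neighbor thermodynamic parameters for DNA/DNA duplexes
# (SantaLucia 1998 unified set; Allawi & SantaLucia 1997 values).
# dH in kcal/mol, dS in cal/(mol*K). Steps are 5'->3' top-strand dinucleotides;
# the parameters of a step equal those of its reverse complement.
# init_A / init_G are duplex-initiation terms per terminal A:T / G:C pair.
# sym is the entropic symmetry correction for self-complementary duplexes.
# columns: key<TAB>dH<TAB>dS
AA	-7.9	-22.2
AT	-7.2	-20.4
TA	-7.2	-21.3
CA	-8.5	-22.7
GT	-8.4	-22.4
CT	-7.8	-21.0
GA	-8.2	-22.2
CG	-10.6	-27.2
GC	-9.8	-24.4
GG	-8.0	-19.9
init_A	2.3	4.1
init_G	0.1	-2.8
sym	0.0	-1.4
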