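# Unified nearest-neighbor parameters for DNA/DNA Watson-Crick duplexes at 1 M NaCl.
# dH in kcal/mol, dS in e.u. (cal/mol/K). Stacks written 5'->3' on the top strand;
# the ten unique stacks are listed, others follow by strand symmetry.
# This set carries the corrected entropies dS(TA/AT) = -21.3 e.u. (not -20.4)
# and dS(GG/CC) = -19.9 e.u. (not -19.0), fixing two values misreproduced in
# older copies of the unified table.
# Initiation terms are per-terminal: init_GC for a G.C end, init_AT for an A.T end.
# provenance: unified oligonucleotide NN set (SantaLucia 1998 / SantaLucia & Hicks 2004)
entry	dH_kcal_mol	dS_eu
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
init_GC	0.1	-2.8
init_AT	2.3	4.1
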