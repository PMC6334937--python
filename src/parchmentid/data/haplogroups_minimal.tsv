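# Minimal sheep mitogenome haplogroup definition table.
# B1a and B1a2a1 carry the published defining polymorphism sets observed in
# the parchment membranes; B and B1a2 are SYNTHETIC intermediate clades
# (subsets constructed for testing the specificity tie-break), not database
# definitions.  Format: haplogroup<TAB>comma-separated variant tokens.
B	281C,566+G,1729+C
B1a	281C,566+G,1729+C,3543A,6615A,7500A,8264C,8651T,9375G,11668A,11710deletion,12539C,12571C,13199G,13813C,14055C,15721C,15783T,15800T,15820T,16128T,16342+C,16343C,16472deletion
B1a2	281C,566+G,1729+C,3543A,6615A,7500A,8264C,8651T,9375G,11668A,11710deletion,12539C,12571C,13199G,13813C,14055C,15721C,15800T,16128T,16342+C,16343C,16472deletion
B1a2a1	281C,566+G,1729+C,3543A,6615A,7500A,7983C,8264C,8651T,9375G,11668A,11710deletion,12539C,12571C,13199G,13813C,14055C,15721C,15800T,16128T,16342+C,16343C,16472deletion
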