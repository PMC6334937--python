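# Published whole-mitogenome polymorphism lists (relative to the sheep
# reference mitogenome) for the three shotgun-sequenced historical parchment
# membranes.  Column 3 holds the haplogroup-defining tokens, column 4 the
# private (not-yet-haplogroup-associated) tokens.  '#' marks a site covered
# by fewer than three reads; '15806' is printed without an allele.
# sample	haplogroup	defining_tokens	private_tokens
upper_membrane	B1a	281C,566+G,1729+C,3543A,6615A,7500A,8264C,8651T,9375G,11668A,11710deletion,12539C,12571C,13199G,13813C,14055C,15721C,15783T,15800T,15820T,16128T,16342+C#,16343C#,16472deletion	732G,1114C,3035C,6375T,10861A,14377G,14683T,14871C,15439C,15658G,15806,16130G,16349T#,16440C
lower_membrane	B1a2a1	281C,566+G,1729+C,3543A,6615A,7500A,7983C,8264C,8651T,9375G,11668A,11710deletion,12539C,12571C,13199G,13813C,14055C,15721C,15800T,16128T,16342+C,16343C,16472deletion	6907R,7573A,8193T,11149G,11653T,12851A,13097A,13489A,15487C,15708C,15787A,15858C,16440C
blank_parchment	B1a2a1	281C,566+G,1729+C,3543A,6615A,7500A,7983C,8264C,8651T,9375G,11668A,11710deletion,12539C,12571C,13199G,13813C,14055C,15721C,15800T,16128T,16342+C,16343C,16472deletion	6907R,7573A,8193T,11149G,11653T,12851A,13097A,13489A,15487C,15708C,15787A,15858C,16440C
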