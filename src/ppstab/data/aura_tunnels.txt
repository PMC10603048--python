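# Surface tunnels of the Aurora A kinase domain, given by their lining
# residues in author numbering.  Tunnel 1 sits at the lower central lobe,
# tunnel 2 at the N-terminal lobe.
tunnel1: E183,I184,H187,L188,K250,V252,H280
tunnel2: K166,L169,L178,V182,V206,L208
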