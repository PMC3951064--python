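# Per-nucleotide counts over the full ORF (stop codon included) of the
# human albumin-superfamily CDSs.
gene	A	T	G	C
ALB	556	488	421	365
AFP	596	465	397	372
AFM	591	502	361	346
VDBP	426	363	305	331
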