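# Alleles that must not be collapsed into their two-field prefix because they
# differ non-synonymously outside the routinely typed exons.  Format:
# FULLNAME<TAB>PRESERVED_LABEL.  A*02:253 is identical to A*02:03 within
# exons 2-3 and is resolved by exon-4 sequencing, so it keeps its own label.
A*02:253	A*02:253
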