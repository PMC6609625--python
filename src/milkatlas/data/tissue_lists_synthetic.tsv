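# SYNTHETIC stand-in tissue proteome lists for demonstrating candidate
# cross-referencing. Real liver / adipose / mammary proteome lists must be
# transcribed from their source supplementary files by the user; only the
# memberships of the six shortlisted proteins are curated here, the rest is
# illustrative filler.
tissue	gene_name	citation_key
liver	ACAT1	liver_proteome
liver	IVD	liver_proteome
liver	LRRC59	liver_proteome
liver	PCK2	liver_proteome
liver	CAT	liver_proteome
liver	ALDH3B1	liver_proteome
adipose	IVD	adipose_proteome
adipose	LRRC59	adipose_proteome
adipose	GPAM	adipose_proteome
adipose	CAT	adipose_proteome
mammary	PCK2	mammary_proteome
mammary	SDHA	mammary_proteome
mammary	UQCRC1	mammary_proteome
mammary	RPL18	mammary_proteome
mammary	EEF1B	mammary_proteome
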