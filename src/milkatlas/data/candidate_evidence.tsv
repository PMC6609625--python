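# Curated evidence flags for the 59 early-lactation candidate proteins.
# tissue_hits and pathway_flags are semicolon-separated; empty = none recorded.
# literature_support = targeted literature/pathway-database mining retained the
# protein as a standalone candidate (complex members whose signal is redundant
# with a sibling subunit are recorded without literature support).
gene_name	tissue_hits	pathway_flags	literature_support	notes
ABCC4				transporter; no energy-metabolism link recorded
ACAT1	liver	ketone_metabolism	true	acetoacetyl-CoA thiolase; ketone-body metabolism in early lactation
ALDH3B1		other		aldehyde oxidation; not retained
ALOX12		other		lipid hydroperoxidation; not retained
ARL6IP5				no energy-metabolism link recorded
ATP5F1		oxidative_phosphorylation		ATP synthase subunit; redundant with complex
ATP5H		oxidative_phosphorylation		ATP synthase subunit; redundant with complex
ATP5J		oxidative_phosphorylation		ATP synthase subunit; redundant with complex
ATP5J2		oxidative_phosphorylation		ATP synthase subunit; redundant with complex
BAT1				no energy-metabolism link recorded
Bt.64131				uncharacterized RAB2A ortholog
C13H20ORF116				uncharacterized
C1QBP		other		ribosome biogenesis annotation; not retained
CAT		other		hydrogen-peroxide detoxification; not retained
COPG				vesicular transport
COX5A		oxidative_phosphorylation		cytochrome c oxidase subunit; redundant with complex
COX5B		oxidative_phosphorylation		cytochrome c oxidase subunit; redundant with complex
COX7A2		oxidative_phosphorylation		cytochrome c oxidase subunit; redundant with complex
CUZD1				uncharacterized
DDRGK1				no energy-metabolism link recorded
DDX39B				RNA helicase
EEF1B				translation elongation
GPAM		other		glycerolipid synthesis; not retained
HIST1H4A				histone
IG				uncharacterized immunoglobulin fragment
IVD	liver;adipose	ketone_metabolism	true	leucine degradation toward HMG-CoA; ketogenic state marker
LF				iron-binding antimicrobial
LMAN1				cargo receptor
LOC789567				uncharacterized
LRPAP1				receptor-associated protein
LRRC59	liver;adipose	cell_proliferation	true	FGF1 nuclear import; mammary epithelial proliferation
Man8				MHC class I antigen
MGC137099				uncharacterized
MYCBP				transcription cofactor
NDUFA5		oxidative_phosphorylation		complex I subunit; redundant with respiratory-chain set
NDUFAB1		oxidative_phosphorylation		mitochondrial acyl carrier; redundant with respiratory-chain set
OSTC				glycosylation
PAFAH1B2				PAF hydrolysis
PCK2	liver;mammary	gluconeogenesis	true	mitochondrial PEPCK; hepatic and mammary gluconeogenic flux
PLSCR2				phospholipid scrambling
RPL10A				60S ribosomal subunit; redundant with complex
RPL18				60S ribosomal subunit; redundant with complex
RPL6				60S ribosomal subunit; redundant with complex
RPL7				60S ribosomal subunit; redundant with complex
RPL7A				60S ribosomal subunit; redundant with complex
RPS13				40S ribosomal subunit
SAA				acute-phase protein
SDHA	mammary	oxidative_phosphorylation	true	complex II flavoprotein; TCA cycle and oxidative metabolism
SEC. 11C		other		signal peptidase; not retained
SEC. 61A1				translocon subunit
SLC15A2				peptide transporter
SSR1				translocon-associated
SURF4				ER cargo receptor
SYPL1				synaptophysin-like
TMED9				vesicular trafficking
TMEM43				membrane protein
TREM1		other		myeloid receptor; not retained
TXNDC4				ER thioredoxin
UQCRC1	mammary	oxidative_phosphorylation	true	complex III core subunit; mitochondrial NADPH-linked oxidative activity
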