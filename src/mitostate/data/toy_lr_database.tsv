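pathway	ligands	receptors	category
ncWNT	Wnt5a	Fzd7	secreted
JAM	F11r	F11r,Jam2	contact
APP	App	Cd74	secreted
COLLAGEN	Col4a3,Col4a4	Itgb1,Itga1	ECM
AGRN	Agrn	Dag1	ECM
ANGPTL	Angptl4	Sdc4	secreted
TGFb	Tgfb1	Tgfbr1,Tgfbr2	secreted
MIF	Mif	Cd74,Cxcr4	secreted
KIT	Kitl	Kit	secreted
VEGF	Vegfa	Flt1	secreted
LAMININ	Lamb2	Dag1	ECM
SELL	Sell	Cd34	contact
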