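ma,tg,ei,cutoff_nM
IC50(nM)p,Caspase-1,B (assay format),1100
IC50(nM)p,Caspase-1,B (single protein format),1100
IC50(nM)p,Caspase-1,B (cell-based format),1100
IC50(nM)p,TNF-alpha,B (single protein format),1635
IC50(nM)p,TNF-alpha,F (assay format),1635
IC50(nM)p,TNF-alpha,B (assay format),1635
IC50(nM)p,TNF-alpha,B (cell-based format),1635
IC50(nM)p,TNF-alpha,F (cell-based format),1635
IC50(nM)p,IGF1R,B (single protein format),50
IC50(nM)p,IGF1R,B (cell-based format),50
IC50(nM)p,IGF1R,B (assay format),50
IC50(nM)p,IGF1R,F (cell-based format),50
IC50(nM)p,IGF1R,F (assay format),50
IC50(nM)c,PSN1,F (cell-based format),6449.735
IC50(nM)c,PANC-03-27,F (cell-based format),6449.735
IC50(nM)c,HPAC,F (cell-based format),6449.735
IC50(nM)c,MZ1-PC,F (cell-based format),6449.735
IC50(nM)c,KP-4,F (cell-based format),6449.735
IC50(nM)c,KP-2,F (cell-based format),6449.735
IC50(nM)c,PA-TU-8988T,F (cell-based format),6449.735
IC50(nM)c,Capan-2,F (cell-based format),6449.735
IC50(nM)c,MIA-PaCa-2,F (cell-based format),6449.735
IC50(nM)c,CFPAC-1,F (cell-based format),6449.735
IC50(nM)c,PANC-10-05,F (cell-based format),6449.735
IC50(nM)c,BxPC-3,F (cell-based format),6449.735
IC50(nM)c,SUIT-2,F (cell-based format),6449.735
IC50(nM)c,KP-1N,F (cell-based format),6449.735
IC50(nM)c,HuP-T4,F (cell-based format),6449.735
IC50(nM)c,SW1990,F (cell-based format),6449.735
IC50(nM)c,PL18,F (cell-based format),6449.735
IC50(nM)c,QGP-1,F (cell-based format),6449.735
IC50(nM)c,HuP-T3,F (cell-based format),6449.735
IC50(nM)c,SU8686,F (cell-based format),6449.735
IC50(nM)c,PL4,F (cell-based format),6449.735
IC50(nM)c,PA-TU-8902,F (cell-based format),6449.735
IC50(nM)c,PANC-02-03,F (cell-based format),6449.735
IC50(nM)c,DAN-G,F (cell-based format),6449.735
IC50(nM)c,CAPAN-1,F (cell-based format),6449.735
IC50(nM)c,PANC-08-13,F (cell-based format),6449.735
IC50(nM)c,HPAF-II,F (cell-based format),6449.735
IC50(nM)c,KP-3,F (cell-based format),6449.735
IC50(nM)c,YAPC,F (cell-based format),6449.735
IC50(nM)c,AsPC-1,F (cell-based format),6449.735
IC50(nM)c,PANC-04-03,F (cell-based format),6449.735
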