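# DSC denaturation parameters of the TmArgBP D2 domain (pH 7.4, 20 mM
# phosphate buffer) across cosolute conditions.  Mixture rows carry a
# composite cosolute label and are excluded from the dCp regression.
cosolute,conc_M,td_C,dh_kJ_mol,dhvh_kJ_mol
buffer,0.0,102.6,470,490
KSCN,0.5,99.6,470,480
KSCN,1.0,97.0,436,450
KSCN,2.0,92.6,425,435
GdmSCN,0.5,90.2,405,409
GdmSCN,1.0,78.4,341,354
GdmSCN,1.5,64.5,256,265
GdmSCN,2.0,50.4,212,223
GdmCl,0.5,98.2,440,458
GdmCl,1.0,94.0,430,439
GdmCl,2.0,86.2,370,390
GdmSCN+TMAO,1.0,84.5,417,426
GdmSCN+sucrose,1.0,85.0,405,412
GdmSCN+TMAO+sucrose,1.0,84.6,417,424
GdmSCN+Na2SO4(0.5M),1.0,91.1,420,415
GdmSCN+Na2SO4(1M),1.0,99.6,417,427
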