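>hs_dhodh_d29_synthetic SYNTHETIC stand-in for the N-terminally truncated human dihydroorotate dehydrogenase construct; 366 residues whose composition reproduces the published molecular volume (~49165 A3) and H2O/D2O SLD contrast series (1.8 -> 3.0 x 1e-6 A-2); not the natural sequence
ASVSDLSFMIDEYISLGKLPIKTIPDSACPVDILVFAIQKRHTVLFVEQSDAPQEGKNAM
PLAAGVIILKVGVPSICMKEFGSKIDAAAVLKWYEGTVQERMLISCDKPARLGTAKVEEG
PYDDLASVPAKLFVLLLLKIIRSGISSATLTFVSQFGAYLVQEGNVIRHDPPDLFDRTLG
CIFDSTHVELSDMELFKPRQRLYIGWKYLSGIAMESIMLSLQKYWVVGLHKAYFQSGQPP
EVMACKVQDVASTNNEFFLADVRTRTIVPVDILLVGQGMNGMTAECEDASEPQNEPVWAI
CDKTVAIGEEAKGYTSKMHQGYFALLDTDDAEHILTFWADPGTILPVMVPEMPMAAATVL
GALLKL
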