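# 212Pb decay chain constants, one row per decay mode.
# Half-lives and branching from NNDC/ENSDF; mean emission energies per decay
# via the given mode (MeV), condensed from ICRP-107-style emission listings.
# 212Po is effectively prompt (0.299 us) and decays in step with 212Bi.
nuclide,half_life_s,mode,daughter,branching,e_alpha_MeV,e_electron_MeV,e_photon_MeV
Pb-212,38304.0,beta,Bi-212,1.0,0.0,0.1752,0.1406
Bi-212,3633.0,beta,Po-212,0.6406,0.0,0.7300,0.1520
Bi-212,3633.0,alpha,Tl-208,0.3594,6.0510,0.0100,0.0160
Po-212,2.99e-7,alpha,Pb-208,1.0,8.7850,0.0,0.0
Tl-208,183.18,beta,Pb-208,1.0,0.0,0.5980,3.3750
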