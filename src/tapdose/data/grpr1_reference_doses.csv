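# Published human-projected absorbed doses for [212Pb]Pb-DOTAM-GRPR1
# (female-mouse projection, RBE 5) at the 0.111 GBq clinically relevant
# administered activity, with the organ dose limits used alongside them.
# These are consumed as inputs; the package's reproducible surface is the
# linear-scaling, activity-limit and safety-margin arithmetic built on them.
organ,dose_gy,dose_limit_gy
kidneys,0.308,23
pancreas,0.287,
liver,0.109,30
stomach,0.044,45
lungs,0.022,65
urinary_bladder,0.021,20
spleen,0.018,26
heart,0.007,45
red_marrow,0.001,2
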