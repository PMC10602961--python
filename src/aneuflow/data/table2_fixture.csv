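row,parameter,before,after,printed_reduction,printed_matches_recomputed
bc_exclusion,ntawss,12.2,3.8,-69,yes
bc_exclusion,lsa,11.1,6.3,-44,no
bc_exclusion,ker,16.2,7.1,-56,yes
bc_exclusion,mean_omega,17.2,13.5,-22,yes
seg_exclusion_bc1,ntawss,31.4,10.8,-66,yes
seg_exclusion_bc1,lsa,35.0,14.3,-59,yes
seg_exclusion_bc1,ker,51.0,11.5,-78,no
seg_exclusion_bc1,mean_omega,21.8,14.5,-33,yes
seg_exclusion_bc2,ntawss,23.9,8.7,-64,yes
seg_exclusion_bc2,lsa,36.9,16.5,-55,yes
seg_exclusion_bc2,ker,38.7,10.6,-73,yes
seg_exclusion_bc2,mean_omega,19.2,12.9,-33,yes
seg_exclusion_bc3,ntawss,28.6,12.7,-56,yes
seg_exclusion_bc3,lsa,37.1,17.2,-54,yes
seg_exclusion_bc3,ker,47.4,14.1,-70,yes
seg_exclusion_bc3,mean_omega,19.4,13.4,-31,yes
seg_exclusion_bc4,ntawss,26.2,11.4,-57,no
seg_exclusion_bc4,lsa,45.0,20.8,-54,yes
seg_exclusion_bc4,ker,40.6,17.6,-57,yes
seg_exclusion_bc4,mean_omega,17.6,8.5,-52,yes
seg_exclusion_bc5,ntawss,21.8,10.1,-53,no
seg_exclusion_bc5,lsa,33.8,19.4,-43,yes
seg_exclusion_bc5,ker,35.7,14.4,-60,yes
seg_exclusion_bc5,mean_omega,15.5,10.2,-34,yes
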