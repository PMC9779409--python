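# Nuclear data for the Rn-222 and Rn-220 decay sub-series.
# Half-lives: ICRP Publication 107. Alpha energies: principal alpha-particle
# energies (MeV per decay); pure beta/gamma emitters carry 0.
# Bi-212 branches: 63.8% beta -> Po-212 (8.78486 MeV alpha), 36.2% alpha
# -> Tl-208; its alpha_energy_MeV is the branch-weighted expectation per
# decay, 0.362 * 6.05 = 2.19010 MeV, so that recursive potential-alpha-energy
# sums need no special casing.
# chain_index follows the conventional 1..5 numbering of each sub-series;
# Po-212 and Tl-208 are parallel terminal branch members, both at index 5.
name,half_life_s,branch_in,alpha_energy_MeV,parent,chain_index
Rn-222,330350.4,1.0,5.4895,,1
Po-218,185.88,1.0,6.00235,Rn-222,2
Pb-214,1608.0,1.0,0.0,Po-218,3
Bi-214,1194.0,1.0,0.0,Pb-214,4
Po-214,1.643e-4,1.0,7.6869,Bi-214,5
Rn-220,55.6,1.0,6.2881,,1
Po-216,0.145,1.0,6.7783,Rn-220,2
Pb-212,38304.0,1.0,0.0,Po-216,3
Bi-212,3633.0,1.0,2.19010,Pb-212,4
Po-212,2.99e-7,0.638,8.78486,Bi-212,5
Tl-208,183.18,0.362,0.0,Bi-212,5
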