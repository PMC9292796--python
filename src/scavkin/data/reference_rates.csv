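medium,mechanism,radical,antioxidant,k_app,gamma_percent,diffusion_controlled
water,HAT,HO,PS,2.61e9,3,true
water,HAT,HO,PSE,2.63e9,3,true
water,HAT,HO,PTE,2.58e9,3,true
water,HAT,HOO,PS,1.96e9,100,true
water,HAT,HOO,PSE,1.98e9,97,true
water,HAT,HOO,PTE,1.96e9,23,true
water,HAT,CH3OO,PS,1.69e9,100,true
water,HAT,CH3OO,PSE,1.69e9,99,true
water,HAT,CH3OO,PTE,1.68e9,32,true
water,RAF,HO,PS,6.94e10,86,true
water,RAF,HO,PSE,7.24e10,87,true
water,RAF,HO,PTE,7.10e10,87,true
water,RAF,HOO,PS,1.67e1,0,false
water,RAF,HOO,PSE,2.60e1,0,false
water,RAF,HOO,PTE,1.55e1,0,false
water,RAF,CH3OO,PS,3.72e-1,0,false
water,RAF,CH3OO,PSE,3.53e-1,0,false
water,RAF,CH3OO,PTE,5.09e-1,0,false
water,SET,HO,PS,8.53e9,11,true
water,SET,HO,PSE,8.47e9,10,true
water,SET,HO,PTE,8.43e9,10,true
water,SET,HOO,PS,3.62e6,0,false
water,SET,HOO,PSE,7.02e7,3,false
water,SET,HOO,PTE,6.76e9,77,true
water,SET,CH3OO,PS,3.85e5,0,false
water,SET,CH3OO,PSE,9.12e6,1,false
water,SET,CH3OO,PTE,3.39e9,68,true
water,overall,HO,PS,8.05e10,,true
water,overall,HO,PSE,8.35e10,,true
water,overall,HO,PTE,8.21e10,,true
water,overall,HOO,PS,1.96e9,,true
water,overall,HOO,PSE,2.05e9,,true
water,overall,HOO,PTE,8.72e9,,true
water,overall,CH3OO,PS,1.69e9,,true
water,overall,CH3OO,PSE,1.70e9,,true
water,overall,CH3OO,PTE,5.07e9,,true
pentyl_ethanoate,HAT,HO,PS,2.87e9,7,true
pentyl_ethanoate,HAT,HO,PSE,2.91e9,7,true
pentyl_ethanoate,HAT,HO,PTE,2.81e9,8,true
pentyl_ethanoate,HAT,HOO,PS,5.63e3,100,false
pentyl_ethanoate,HAT,HOO,PSE,3.66e3,100,false
pentyl_ethanoate,HAT,HOO,PTE,1.24e3,100,false
pentyl_ethanoate,HAT,CH3OO,PS,1.55e3,100,false
pentyl_ethanoate,HAT,CH3OO,PSE,9.06e2,100,false
pentyl_ethanoate,HAT,CH3OO,PTE,3.95e2,100,false
pentyl_ethanoate,RAF,HO,PS,3.80e10,93,true
pentyl_ethanoate,RAF,HO,PSE,3.78e10,93,true
pentyl_ethanoate,RAF,HO,PTE,3.33e10,92,true
pentyl_ethanoate,RAF,HOO,PS,4.32e-2,0,false
pentyl_ethanoate,RAF,HOO,PSE,5.04e-2,0,false
pentyl_ethanoate,RAF,HOO,PTE,4.47e-2,0,false
pentyl_ethanoate,RAF,CH3OO,PS,1.86e-4,0,false
pentyl_ethanoate,RAF,CH3OO,PSE,2.13e-4,0,false
pentyl_ethanoate,RAF,CH3OO,PTE,3.50e-4,0,false
pentyl_ethanoate,SET,HO,PS,8.80e-19,0,false
pentyl_ethanoate,SET,HO,PSE,6.84e-15,0,false
pentyl_ethanoate,SET,HO,PTE,7.45e-22,0,false
pentyl_ethanoate,SET,HOO,PS,2.60e-31,0,false
pentyl_ethanoate,SET,HOO,PSE,2.87e-28,0,false
pentyl_ethanoate,SET,HOO,PTE,9.60e-30,0,false
pentyl_ethanoate,SET,CH3OO,PS,9.24e-33,0,false
pentyl_ethanoate,SET,CH3OO,PSE,1.13e-29,0,false
pentyl_ethanoate,SET,CH3OO,PTE,2.65e-31,0,false
pentyl_ethanoate,overall,HO,PS,4.09e10,,true
pentyl_ethanoate,overall,HO,PSE,4.07e10,,true
pentyl_ethanoate,overall,HO,PTE,3.61e10,,true
pentyl_ethanoate,overall,HOO,PS,5.63e3,,false
pentyl_ethanoate,overall,HOO,PSE,3.66e3,,false
pentyl_ethanoate,overall,HOO,PTE,1.24e3,,false
pentyl_ethanoate,overall,CH3OO,PS,1.55e3,,false
pentyl_ethanoate,overall,CH3OO,PSE,9.06e2,,false
pentyl_ethanoate,overall,CH3OO,PTE,3.95e2,,false
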