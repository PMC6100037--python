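# Default volatile-compound panel for table grapes: identity, chemical class,
# odor threshold in ug/kg (literature consensus values), pipe-separated odor
# descriptors. Intended as a ready-to-use example panel; project-specific
# panels replace this file via load_compound_library().
compound_id,name,class,threshold_ug_per_kg,descriptors
hexanal,hexanal,C6,4.5,green|grass
e2_hexenal,(E)-2-hexenal,C6,17,green|apple
hexanol,1-hexanol,C6,8000,green
z3_hexenol,(Z)-3-hexen-1-ol,C6,400,grass
e2_hexenol,(E)-2-hexen-1-ol,C6,8000,green|leafy
octanal,octanal,aldehyde,0.7,citrus|fatty
nonanal,nonanal,aldehyde,1,citrus|waxy
decanal,decanal,aldehyde,2,orange|waxy
benzaldehyde,benzaldehyde,aldehyde,350,nutty|roasted
ethyl_acetate,ethyl acetate,ester,7500,solvent|pineapple
ethyl_propionate,ethyl propionate,ester,10,banana|apple|strawberry
ethyl_butyrate,ethyl butyrate,ester,1,apple|pineapple
ethyl_2mb,ethyl 2-methylbutanoate,ester,0.1,apple|strawberry
ethyl_3mb,ethyl 3-methylbutanoate,ester,0.02,apple|grape
ethyl_hexanoate,ethyl hexanoate,ester,1,apple|banana
hexyl_acetate,hexyl acetate,ester,1.5,apple|banana
methyl_anthranilate,methyl anthranilate,ester,3,grape
linalool,linalool,terpene,6,floral|lavender
geraniol,geraniol,terpene,30,rose|geranium
citronellol,citronellol,terpene,100,rose
nerol,nerol,terpene,400,rose|orange_flower
d_limonene,d-limonene,terpene,10,citrus|orange
terpinolene,terpinolene,terpene,200,pine
rose_oxide_1,rose oxide I (trans),terpene,0.2,rose|geranium
cedrol,cedrol,terpene,0.5,woody|balsamic
geranic_acid,geranic acid,terpene,40,floral|green
b_damascenone,beta-damascenone,C13_norisoprenoid,0.05,apple|rose|honey
b_ionone,beta-ionone,C13_norisoprenoid,0.09,violet
hexanoic_acid,hexanoic acid,acid,3000,fatty|cheesy
octanoic_acid,octanoic acid,acid,3000,fatty|oily
heptanone_2,2-heptanone,ketone,140,banana|cheesy
acetoin,acetoin,ketone,800,caramel
heptanol_2,2-heptanol,alcohol,70,mushroom|oily
benzyl_alcohol,benzyl alcohol,alcohol,200000,floral
phenylethanol_2,2-phenylethanol,alcohol,1000,rose|honey
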