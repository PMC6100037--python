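# Default aromatic-series taxonomy: odor descriptor -> primary series (and,
# for fruity/floral/sweet, pipe-separated secondary series).
# The fruity/floral/sweet branches carry 14/13/5 secondary series; the named
# ones are the series the literature spells out, the *_x* entries are clearly
# labelled placeholders completing the counts and are replaceable by a user
# taxonomy file.
descriptor,primary_series,secondary_series
apple,fruity,apple
citrus,fruity,citrus
orange,fruity,orange
lemon,fruity,lemon
grape,fruity,grape
banana,fruity,banana
strawberry,fruity,strawberry
pineapple,fruity,pineapple
fruity_x1,fruity,fruity_x1
fruity_x2,fruity,fruity_x2
fruity_x3,fruity,fruity_x3
fruity_x4,fruity,fruity_x4
fruity_x5,fruity,fruity_x5
fruity_x6,fruity,fruity_x6
rose,floral,rose
geranium,floral,geranium
violet,floral,violet
lavender,floral,lavender
orange_flower,floral,orange_flower
floral_x1,floral,floral_x1
floral_x2,floral,floral_x2
floral_x3,floral,floral_x3
floral_x4,floral,floral_x4
floral_x5,floral,floral_x5
floral_x6,floral,floral_x6
floral_x7,floral,floral_x7
floral_x8,floral,floral_x8
honey,sweet,honey
marshmallow,sweet,marshmallow
sweet_x1,sweet,sweet_x1
sweet_x2,sweet,sweet_x2
sweet_x3,sweet,sweet_x3
fruity,fruity,
floral,floral,
sweet,sweet,
caramel,sweet,
vanilla,sweet,
green,herbaceous,
grass,herbaceous,
leafy,herbaceous,
herbaceous,herbaceous,
spicy,spicy,
pepper,spicy,
clove,spicy,
roasted,roasty,
toasted,roasty,
nutty,roasty,
fatty,fatty,
waxy,fatty,
oily,fatty,
cheesy,fatty,
earthy,earthy,
mushroom,earthy,
musty,earthy,
balsamic,balsamic,
pine,balsamic,
resin,balsamic,
woody,balsamic,
solvent,solvent,
ethereal,solvent,
pungent,solvent,
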