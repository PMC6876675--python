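# Default food-group map, version 1.
#
# `categories` are the 12 food categories of the survey instrument, in column
# order.  Each scheme maps its groups to one or more categories; a category
# may appear in several schemes (or in none, e.g. oil is not a child-diet
# group).  `fcs_weights` are the standard WFP/HKI food-consumption-score
# group weights, with sugar folded into the oil group.
version: 1
categories:
  - cereals
  - white_roots_tubers
  - vitaminA_vegetables
  - other_vegetables
  - vitaminA_fruits
  - other_fruits
  - organ_meat
  - flesh_meat_fish
  - eggs
  - legumes_nuts
  - milk_dairy
  - oils_fats
schemes:
  hdds:
    starchy_staples: [cereals, white_roots_tubers]
    legumes_nuts: [legumes_nuts]
    milk_dairy: [milk_dairy]
    vegetables: [vitaminA_vegetables, other_vegetables]
    fruits: [vitaminA_fruits, other_fruits]
    meat: [organ_meat, flesh_meat_fish]
    eggs: [eggs]
    oil: [oils_fats]
  cdds:
    grains_roots_tubers: [cereals, white_roots_tubers]
    legumes_nuts: [legumes_nuts]
    dairy: [milk_dairy]
    flesh_foods: [flesh_meat_fish]
    eggs: [eggs]
    vitaminA_fruits_vegetables: [vitaminA_vegetables, vitaminA_fruits]
    other_fruits_vegetables: [other_vegetables, other_fruits]
    organ_meat: [organ_meat]
  fgds:
    starchy_staples: [cereals, white_roots_tubers]
    legumes_nuts: [legumes_nuts]
    dairy: [milk_dairy]
    organ_meat: [organ_meat]
    eggs: [eggs]
    flesh_foods: [flesh_meat_fish]
    vitaminA_fruits: [vitaminA_fruits]
    vitaminA_vegetables: [vitaminA_vegetables]
    other_fruits_vegetables: [other_vegetables, other_fruits]
    oil: [oils_fats]
  vitamin_a:
    vitaminA_fruits: [vitaminA_fruits]
    vitaminA_vegetables: [vitaminA_vegetables]
    eggs: [eggs]
    dairy: [milk_dairy]
    red_meat: [flesh_meat_fish]
    organ_meat: [organ_meat]
  fcs:
    staples: [cereals, white_roots_tubers]
    pulses: [legumes_nuts]
    vegetables: [vitaminA_vegetables, other_vegetables]
    fruit: [vitaminA_fruits, other_fruits]
    meat_fish: [organ_meat, flesh_meat_fish, eggs]
    milk: [milk_dairy]
    oil: [oils_fats]
fcs_weights:
  staples: 2.0
  pulses: 3.0
  vegetables: 1.0
  fruit: 1.0
  meat_fish: 4.0
  milk: 4.0
  oil: 0.5
vitamin_a_items:
  - vitaminA_vegetables
  - vitaminA_fruits
  - organ_meat
  - flesh_meat_fish
  - eggs
  - milk_dairy
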