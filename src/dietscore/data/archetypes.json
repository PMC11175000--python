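{
  "comment": "Default generator parameters. Item means are weekly frequencies: the md archetype sits at or inside every favorable MEDOC cut-off (Mediterranean pattern), the wd archetype at representative Western-pattern values; dispersion d gives negative-binomial variance mean + d*mean^2, calibrated so simulated SD/mean ratios match those observed for weekly FFQ counts. A mixed(lambda) archetype interpolates item means and behavior probabilities linearly.",
  "dispersion": 0.5,
  "portion_probs": {
    "md": {"small": 0.2, "standard": 0.6, "large": 0.2},
    "wd": {"small": 0.15, "standard": 0.5, "large": 0.35}
  },
  "behavior_favorable": {
    "seasonality": "seasonal",
    "cereal_type": "non_refined",
    "olive_oil": "regular_frequent",
    "dairy_fat": "skimmed",
    "fish_source": "local_producer",
    "white_meat_source": "local_producer",
    "red_meat_source": "local_producer",
    "sweets_type": "homemade",
    "has_breakfast": "yes",
    "meal_time": "at_least_30_min",
    "nibbling": "no",
    "spices_instead_of_salt": "yes",
    "dining_out": "under_4_per_week"
  },
  "behavior_favorable_p": {"md": 0.85, "wd": 0.15},
  "item_means": {
    "medium_large_fruit": {"md": 10.0, "wd": 2.0},
    "small_fruit": {"md": 8.0, "wd": 1.0},
    "dried_fruit": {"md": 3.0, "wd": 1.0},
    "cooked_vegetables": {"md": 10.0, "wd": 2.0},
    "raw_vegetables": {"md": 7.0, "wd": 1.5},
    "salad": {"md": 7.0, "wd": 1.0},
    "potatoes": {"md": 2.0, "wd": 2.0},
    "french_fries": {"md": 0.3, "wd": 2.0},
    "breakfast_cereals": {"md": 5.0, "wd": 1.0},
    "loaf_bread": {"md": 1.0, "wd": 5.0},
    "fresh_bread": {"md": 9.0, "wd": 2.0},
    "bread_substitutes": {"md": 0.5, "wd": 4.0},
    "focaccia_bread": {"md": 0.5, "wd": 2.0},
    "pizza": {"md": 1.0, "wd": 2.0},
    "rice_other_cereals": {"md": 7.0, "wd": 1.5},
    "pasta": {"md": 7.0, "wd": 5.5},
    "cookies": {"md": 0.5, "wd": 5.0},
    "sweets_cakes_pastries": {"md": 0.5, "wd": 4.0},
    "cow_milk": {"md": 5.0, "wd": 3.0},
    "milk_products": {"md": 5.0, "wd": 2.0},
    "fresh_cheese": {"md": 2.0, "wd": 3.0},
    "seasoned_cheese": {"md": 2.0, "wd": 3.0},
    "white_meat": {"md": 2.0, "wd": 4.0},
    "red_meat": {"md": 1.0, "wd": 4.0},
    "ultra_processed_food": {"md": 0.5, "wd": 4.0},
    "fresh_fish": {"md": 1.5, "wd": 0.5},
    "tinned_fish": {"md": 1.0, "wd": 0.5},
    "eggs": {"md": 3.0, "wd": 1.0},
    "legumes": {"md": 3.0, "wd": 0.5},
    "soda": {"md": 0.2, "wd": 4.0},
    "wine": {"md": 2.0, "wd": 1.0},
    "beer": {"md": 0.5, "wd": 2.0},
    "cocktail": {"md": 0.2, "wd": 1.5},
    "spirits": {"md": 0.1, "wd": 0.5},
    "fast_food": {"md": 0.1, "wd": 2.0},
    "salted_snack": {"md": 0.3, "wd": 3.0},
    "frozen_foods": {"md": 0.3, "wd": 2.0},
    "ready_to_eat_meals": {"md": 0.3, "wd": 2.5},
    "breakfast_croissant_cappuccino": {"md": 0.5, "wd": 4.0}
  },
  "age_strata": {
    "young_adults": {"weight": 0.681, "mean": 22.91, "sd": 2.25, "min": 18.0, "max": 30.0},
    "adults_elderly": {"weight": 0.319, "mean": 56.33, "sd": 17.43, "min": 31.0, "max": 95.0}
  },
  "sex_probs": {"F": 0.7, "M": 0.3},
  "stratum_mixtures": {
    "young_adults": {"md": 0.25, "mixed": 0.45, "wd": 0.30},
    "adults_elderly": {"md": 0.45, "mixed": 0.40, "wd": 0.15}
  },
  "retest_noise": {"tau": 0.8, "portion_switch_p": 0.25, "behavior_flip_p": 0.15}
}
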