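{
  "name": "medilite-default",
  "comment": "Nine MEDILITE food groups scored 0/1/2. MD-typical groups: highest consumption level scores 2; non-MD groups: lowest level scores 2; alcohol: middle level scores 2, lowest 1, highest 0. Cut points c1 < c2 define lowest (< c1), middle ([c1, c2]) and highest (> c2) consumption; defaults expressed in weekly servings except alcohol (units/day). Olive oil is resolved from the olive-oil use behavior (occasional -> lowest, regular/frequent -> highest).",
  "groups": [
    {"group_id": "fruit", "group_class": "md_typical", "unit": "weekly_servings", "items": ["medium_large_fruit", "small_fruit", "dried_fruit"], "cuts": [10.5, 17.5]},
    {"group_id": "vegetables", "group_class": "md_typical", "unit": "weekly_servings", "items": ["cooked_vegetables", "raw_vegetables", "salad"], "cuts": [10.5, 17.5]},
    {"group_id": "legumes", "group_class": "md_typical", "unit": "weekly_servings", "items": ["legumes"], "cuts": [1.0, 2.0]},
    {"group_id": "cereals", "group_class": "md_typical", "unit": "weekly_servings", "items": ["breakfast_cereals", "fresh_bread", "rice_other_cereals", "pasta"], "cuts": [7.0, 10.5]},
    {"group_id": "fish", "group_class": "md_typical", "unit": "weekly_servings", "items": ["fresh_fish", "tinned_fish"], "cuts": [1.0, 2.5]},
    {"group_id": "meat", "group_class": "non_md", "unit": "weekly_servings", "items": ["red_meat", "white_meat", "ultra_processed_food"], "cuts": [7.0, 10.5]},
    {"group_id": "dairy", "group_class": "non_md", "unit": "weekly_servings", "items": ["cow_milk", "milk_products", "fresh_cheese", "seasoned_cheese"], "cuts": [7.0, 10.5]},
    {"group_id": "alcohol", "group_class": "alcohol", "unit": "units_per_day", "items": ["wine", "beer", "cocktail", "spirits"], "cuts": [1.0, 2.0]},
    {"group_id": "olive_oil", "group_class": "md_typical", "unit": "behavior", "behavior": "olive_oil", "behavior_levels": {"regular_frequent": "highest", "occasional": "lowest"}}
  ]
}
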