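{
  "name": "meddietscore-default",
  "comment": "Eleven MedDietScore components, each scored 0..5. Pro-MD and anti-MD components are binned on monthly servings (weekly intake x 4); potatoes use weekly servings with the published 3-4/week optimum; alcohol uses wine glasses per day; olive oil is scored from the olive-oil use behavior answer.",
  "weekly_to_monthly": 4.0,
  "components": [
    {
      "component_id": "non_refined_cereals",
      "direction": "pro",
      "unit": "monthly_servings",
      "items": ["breakfast_cereals", "fresh_bread", "rice_other_cereals", "pasta"],
      "bins": [
        {"max": 1, "closed": false, "score": 0},
        {"max": 5, "closed": false, "score": 1},
        {"max": 9, "closed": false, "score": 2},
        {"max": 13, "closed": false, "score": 3},
        {"max": 19, "closed": false, "score": 4},
        {"max": null, "score": 5}
      ]
    },
    {
      "component_id": "fruit",
      "direction": "pro",
      "unit": "monthly_servings",
      "items": ["medium_large_fruit", "small_fruit", "dried_fruit"],
      "bins": [
        {"max": 1, "closed": false, "score": 0},
        {"max": 5, "closed": false, "score": 1},
        {"max": 9, "closed": false, "score": 2},
        {"max": 13, "closed": false, "score": 3},
        {"max": 19, "closed": false, "score": 4},
        {"max": null, "score": 5}
      ]
    },
    {
      "component_id": "vegetables",
      "direction": "pro",
      "unit": "monthly_servings",
      "items": ["cooked_vegetables", "raw_vegetables", "salad"],
      "bins": [
        {"max": 1, "closed": false, "score": 0},
        {"max": 5, "closed": false, "score": 1},
        {"max": 9, "closed": false, "score": 2},
        {"max": 13, "closed": false, "score": 3},
        {"max": 19, "closed": false, "score": 4},
        {"max": null, "score": 5}
      ]
    },
    {
      "component_id": "legumes",
      "direction": "pro",
      "unit": "monthly_servings",
      "items": ["legumes"],
      "bins": [
        {"max": 1, "closed": false, "score": 0},
        {"max": 5, "closed": false, "score": 1},
        {"max": 9, "closed": false, "score": 2},
        {"max": 13, "closed": false, "score": 3},
        {"max": 19, "closed": false, "score": 4},
        {"max": null, "score": 5}
      ]
    },
    {
      "component_id": "fish",
      "direction": "pro",
      "unit": "monthly_servings",
      "items": ["fresh_fish", "tinned_fish"],
      "bins": [
        {"max": 1, "closed": false, "score": 0},
        {"max": 5, "closed": false, "score": 1},
        {"max": 9, "closed": false, "score": 2},
        {"max": 13, "closed": false, "score": 3},
        {"max": 19, "closed": false, "score": 4},
        {"max": null, "score": 5}
      ]
    },
    {
      "component_id": "meat_products",
      "direction": "anti",
      "unit": "monthly_servings",
      "items": ["red_meat", "ultra_processed_food"],
      "bins": [
        {"max": 1, "closed": false, "score": 5},
        {"max": 5, "closed": false, "score": 4},
        {"max": 9, "closed": false, "score": 3},
        {"max": 13, "closed": false, "score": 2},
        {"max": 19, "closed": false, "score": 1},
        {"max": null, "score": 0}
      ]
    },
    {
      "component_id": "poultry",
      "direction": "anti",
      "unit": "monthly_servings",
      "items": ["white_meat"],
      "bins": [
        {"max": 1, "closed": false, "score": 5},
        {"max": 5, "closed": false, "score": 4},
        {"max": 9, "closed": false, "score": 3},
        {"max": 13, "closed": false, "score": 2},
        {"max": 19, "closed": false, "score": 1},
        {"max": null, "score": 0}
      ]
    },
    {
      "component_id": "full_fat_dairy",
      "direction": "anti",
      "unit": "monthly_servings",
      "items": ["cow_milk", "milk_products", "fresh_cheese", "seasoned_cheese"],
      "bins": [
        {"max": 1, "closed": false, "score": 5},
        {"max": 5, "closed": false, "score": 4},
        {"max": 9, "closed": false, "score": 3},
        {"max": 13, "closed": false, "score": 2},
        {"max": 19, "closed": false, "score": 1},
        {"max": null, "score": 0}
      ]
    },
    {
      "component_id": "potatoes",
      "direction": "special_potato",
      "unit": "weekly_servings",
      "items": ["potatoes"],
      "bins": [
        {"max": 1, "closed": false, "score": 3},
        {"max": 3, "closed": false, "score": 4},
        {"max": 5, "closed": false, "score": 5},
        {"max": 6.5, "closed": false, "score": 2},
        {"max": 7, "closed": false, "score": 1},
        {"max": null, "score": 0}
      ]
    },
    {
      "component_id": "alcohol",
      "direction": "special_alcohol",
      "unit": "glasses_per_day",
      "items": ["wine", "beer", "cocktail", "spirits"],
      "bins": [
        {"max": 3, "closed": false, "score": 5},
        {"max": 4, "closed": false, "score": 4},
        {"max": 6, "closed": false, "score": 3},
        {"max": 7, "closed": false, "score": 2},
        {"max": 7, "closed": true, "score": 1},
        {"max": null, "score": 0}
      ]
    },
    {
      "component_id": "olive_oil",
      "direction": "pro",
      "unit": "behavior",
      "behavior": "olive_oil",
      "behavior_scores": {"regular_frequent": 5, "occasional": 2}
    }
  ]
}
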