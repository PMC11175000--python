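{
  "name": "medoc-default",
  "portion_levels": [
    {"label": "small", "multiplier": 0.5},
    {"label": "standard", "multiplier": 1.0},
    {"label": "large", "multiplier": 1.5}
  ],
  "items": [
    {"id": "medium_large_fruit", "label": "Medium/large sized fruit", "category": "vegetables_fruits", "has_portion_question": true},
    {"id": "small_fruit", "label": "Small sized fruit", "category": "vegetables_fruits", "has_portion_question": true},
    {"id": "dried_fruit", "label": "Dried fruit", "category": "vegetables_fruits", "has_portion_question": false},
    {"id": "cooked_vegetables", "label": "Cooked vegetables", "category": "vegetables_fruits", "has_portion_question": true},
    {"id": "raw_vegetables", "label": "Raw vegetables", "category": "vegetables_fruits", "has_portion_question": true},
    {"id": "salad", "label": "Salad", "category": "vegetables_fruits", "has_portion_question": true},
    {"id": "potatoes", "label": "Potatoes", "category": "vegetables_fruits", "has_portion_question": true},
    {"id": "french_fries", "label": "French fries", "category": "vegetables_fruits", "has_portion_question": true},
    {"id": "breakfast_cereals", "label": "Breakfast cereals", "category": "cereals", "has_portion_question": true},
    {"id": "loaf_bread", "label": "Loaf bread", "category": "cereals", "has_portion_question": true},
    {"id": "fresh_bread", "label": "Fresh bread", "category": "cereals", "has_portion_question": true},
    {"id": "bread_substitutes", "label": "Bread substitutes", "category": "cereals", "has_portion_question": true},
    {"id": "focaccia_bread", "label": "Focaccia bread", "category": "cereals", "has_portion_question": true},
    {"id": "pizza", "label": "Pizza", "category": "cereals", "has_portion_question": true},
    {"id": "rice_other_cereals", "label": "Rice and other cereals", "category": "cereals", "has_portion_question": true},
    {"id": "pasta", "label": "Pasta", "category": "cereals", "has_portion_question": true},
    {"id": "cookies", "label": "Cookies", "category": "cereals", "has_portion_question": true},
    {"id": "sweets_cakes_pastries", "label": "Sweets/cakes/pastries", "category": "cereals", "has_portion_question": true},
    {"id": "cow_milk", "label": "Cow milk", "category": "dairy", "has_portion_question": true},
    {"id": "milk_products", "label": "Milk products", "category": "dairy", "has_portion_question": true},
    {"id": "fresh_cheese", "label": "Fresh cheese", "category": "dairy", "has_portion_question": true},
    {"id": "seasoned_cheese", "label": "Seasoned cheese", "category": "dairy", "has_portion_question": true},
    {"id": "white_meat", "label": "White meat", "category": "meat_fish", "has_portion_question": true},
    {"id": "red_meat", "label": "Red meat", "category": "meat_fish", "has_portion_question": true},
    {"id": "ultra_processed_food", "label": "Ultra-processed food", "category": "meat_fish", "has_portion_question": true},
    {"id": "fresh_fish", "label": "Fresh fish", "category": "meat_fish", "has_portion_question": true},
    {"id": "tinned_fish", "label": "Tinned fish", "category": "meat_fish", "has_portion_question": true},
    {"id": "eggs", "label": "Eggs", "category": "meat_fish", "has_portion_question": true},
    {"id": "legumes", "label": "Legumes", "category": "meat_fish", "has_portion_question": true},
    {"id": "soda", "label": "Soda", "category": "drinks", "has_portion_question": true},
    {"id": "wine", "label": "Wine", "category": "drinks", "has_portion_question": true},
    {"id": "beer", "label": "Beer", "category": "drinks", "has_portion_question": true},
    {"id": "cocktail", "label": "Cocktail", "category": "drinks", "has_portion_question": true},
    {"id": "spirits", "label": "Spirits", "category": "drinks", "has_portion_question": false},
    {"id": "fast_food", "label": "Fast food", "category": "unhealthy", "has_portion_question": true},
    {"id": "salted_snack", "label": "Salted snack", "category": "unhealthy", "has_portion_question": true},
    {"id": "frozen_foods", "label": "Frozen foods", "category": "unhealthy", "has_portion_question": false},
    {"id": "ready_to_eat_meals", "label": "Ready-to-eat meals", "category": "unhealthy", "has_portion_question": false},
    {"id": "breakfast_croissant_cappuccino", "label": "Breakfast with croissant and cappuccino", "category": "unhealthy", "has_portion_question": false}
  ],
  "behavior_questions": [
    {"id": "seasonality", "label": "Fruit and vegetables are mostly seasonal", "answers": ["seasonal", "not_seasonal"]},
    {"id": "cereal_type", "label": "Cereals are mostly refined or non-refined", "answers": ["non_refined", "refined"]},
    {"id": "olive_oil", "label": "Olive oil consumption", "answers": ["regular_frequent", "occasional"]},
    {"id": "dairy_fat", "label": "Dairy is mostly skimmed/partially skimmed or full fat", "answers": ["skimmed", "full_fat"]},
    {"id": "fish_source", "label": "Fish is bought from a local producer or a supermarket", "answers": ["local_producer", "supermarket"]},
    {"id": "white_meat_source", "label": "White meat is bought from a local producer or a supermarket", "answers": ["local_producer", "supermarket"]},
    {"id": "red_meat_source", "label": "Red meat is bought from a local producer or a supermarket", "answers": ["local_producer", "supermarket"]},
    {"id": "sweets_type", "label": "Sweets are mostly homemade or packed", "answers": ["homemade", "packed"]},
    {"id": "has_breakfast", "label": "Eats breakfast", "answers": ["yes", "no"]},
    {"id": "meal_time", "label": "Time dedicated to meals", "answers": ["at_least_30_min", "under_30_min"]},
    {"id": "nibbling", "label": "Nibbles between meals", "answers": ["no", "yes"]},
    {"id": "spices_instead_of_salt", "label": "Adds spices instead of salt", "answers": ["yes", "no"]},
    {"id": "dining_out", "label": "Dining out / takeaway frequency", "answers": ["under_4_per_week", "at_least_4_per_week"]}
  ],
  "aggregation_map": {
    "fruits_vegetables": ["medium_large_fruit", "small_fruit", "cooked_vegetables", "raw_vegetables", "salad"],
    "cereals": ["breakfast_cereals", "fresh_bread", "rice_other_cereals", "pasta"],
    "dairy": ["cow_milk", "milk_products", "fresh_cheese", "seasoned_cheese"],
    "eggs": ["eggs"],
    "legumes": ["legumes"],
    "fish": ["fresh_fish", "tinned_fish"],
    "white_meat": ["white_meat"],
    "red_meat": ["red_meat"],
    "processed_meat": ["ultra_processed_food"],
    "sweets": ["cookies", "sweets_cakes_pastries"],
    "breakfast_croissant": ["breakfast_croissant_cappuccino"],
    "bread_substitutes": ["bread_substitutes"],
    "fast_food": ["fast_food"],
    "salted_snacks": ["salted_snack"],
    "sodas": ["soda"],
    "ready_to_eat": ["ready_to_eat_meals", "frozen_foods"]
  }
}
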