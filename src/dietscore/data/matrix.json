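{
  "name": "medoc-default",
  "rules": [
    {
      "row_id": "fruits_vegetables",
      "label": "Fruits/Vegetables",
      "kind": "frequency_range",
      "unit": "per_day",
      "cutoff_text": ">=5 servings/day",
      "favorable": {"lo": 35.0, "lo_closed": true, "hi": null, "hi_closed": false},
      "modifier": {"behavior": "seasonality", "favorable_answer": "seasonal", "unfavorable_answer": "not_seasonal"}
    },
    {
      "row_id": "cereals",
      "label": "Cereals",
      "kind": "frequency_range",
      "unit": "per_day",
      "cutoff_text": "3-6 servings/day",
      "favorable": {"lo": 21.0, "lo_closed": true, "hi": 42.0, "hi_closed": true},
      "modifier": {"behavior": "cereal_type", "favorable_answer": "non_refined", "unfavorable_answer": "refined"}
    },
    {
      "row_id": "olive_oil",
      "label": "Olive oil",
      "kind": "categorical",
      "behavior": "olive_oil",
      "favorable_answer": "regular_frequent",
      "modifier": null
    },
    {
      "row_id": "dairy",
      "label": "Dairy",
      "kind": "frequency_range",
      "unit": "per_day",
      "cutoff_text": "2 servings/day",
      "favorable": {"lo": 14.0, "lo_closed": true, "hi": 14.0, "hi_closed": true},
      "modifier": {"behavior": "dairy_fat", "favorable_answer": "skimmed", "unfavorable_answer": "full_fat"}
    },
    {
      "row_id": "eggs",
      "label": "Eggs",
      "kind": "frequency_range",
      "unit": "per_week",
      "cutoff_text": "2-4 servings/week",
      "favorable": {"lo": 2.0, "lo_closed": true, "hi": 4.0, "hi_closed": true},
      "modifier": null
    },
    {
      "row_id": "legumes",
      "label": "Legumes",
      "kind": "frequency_range",
      "unit": "per_week",
      "cutoff_text": ">=2 servings/week",
      "favorable": {"lo": 2.0, "lo_closed": true, "hi": null, "hi_closed": false},
      "modifier": null
    },
    {
      "row_id": "fish",
      "label": "Fish",
      "kind": "frequency_range",
      "unit": "per_week",
      "cutoff_text": ">=2 servings/week",
      "favorable": {"lo": 2.0, "lo_closed": true, "hi": null, "hi_closed": false},
      "modifier": {"behavior": "fish_source", "favorable_answer": "local_producer", "unfavorable_answer": "supermarket"}
    },
    {
      "row_id": "white_meat",
      "label": "White meat",
      "kind": "frequency_range",
      "unit": "per_week",
      "cutoff_text": "2 servings/week",
      "favorable": {"lo": 2.0, "lo_closed": true, "hi": 2.0, "hi_closed": true},
      "modifier": {"behavior": "white_meat_source", "favorable_answer": "local_producer", "unfavorable_answer": "supermarket"}
    },
    {
      "row_id": "red_meat",
      "label": "Red meat",
      "kind": "frequency_range",
      "unit": "per_week",
      "cutoff_text": "<2 servings/week",
      "favorable": {"lo": 0.0, "lo_closed": true, "hi": 2.0, "hi_closed": false},
      "modifier": {"behavior": "red_meat_source", "favorable_answer": "local_producer", "unfavorable_answer": "supermarket"}
    },
    {
      "row_id": "processed_meat",
      "label": "Processed meat",
      "kind": "frequency_range",
      "unit": "per_week",
      "cutoff_text": "<=1 servings/week",
      "favorable": {"lo": 0.0, "lo_closed": true, "hi": 1.0, "hi_closed": true},
      "modifier": null
    },
    {
      "row_id": "sweets",
      "label": "Sweets/cakes/pastries",
      "kind": "frequency_range",
      "unit": "per_week",
      "cutoff_text": "<=2 servings/week",
      "favorable": {"lo": 0.0, "lo_closed": true, "hi": 2.0, "hi_closed": true},
      "modifier": {"behavior": "sweets_type", "favorable_answer": "homemade", "unfavorable_answer": "packed"}
    },
    {
      "row_id": "breakfast_croissant",
      "label": "Breakfast with croissant and cappuccino",
      "kind": "frequency_range",
      "unit": "per_week",
      "cutoff_text": "0-1 times/week (no breakfast counts as unfavorable)",
      "favorable": {"lo": 0.0, "lo_closed": true, "hi": 1.0, "hi_closed": true},
      "modifier": null,
      "gate": {"behavior": "has_breakfast", "unfavorable_answer": "no"}
    },
    {
      "row_id": "time_meals",
      "label": "Time dedicated to meals",
      "kind": "categorical",
      "behavior": "meal_time",
      "favorable_answer": "at_least_30_min",
      "modifier": null
    },
    {
      "row_id": "nibbling",
      "label": "Nibbling",
      "kind": "categorical",
      "behavior": "nibbling",
      "favorable_answer": "no",
      "modifier": null
    },
    {
      "row_id": "spices",
      "label": "Adding spices instead of salt",
      "kind": "categorical",
      "behavior": "spices_instead_of_salt",
      "favorable_answer": "yes",
      "modifier": null
    },
    {
      "row_id": "dining_out",
      "label": "Dining out/takeaway",
      "kind": "categorical",
      "behavior": "dining_out",
      "favorable_answer": "under_4_per_week",
      "modifier": null
    },
    {
      "row_id": "bread",
      "label": "Bread (loaf vs fresh)",
      "kind": "comparison",
      "left_item": "loaf_bread",
      "right_item": "fresh_bread",
      "cutoff_text": "weekly frequency of loaf bread <= fresh bread",
      "modifier": null
    },
    {
      "row_id": "bread_substitutes",
      "label": "Bread substitutes",
      "kind": "frequency_range",
      "unit": "per_week",
      "cutoff_text": "<=1 times/week",
      "favorable": {"lo": 0.0, "lo_closed": true, "hi": 1.0, "hi_closed": true},
      "modifier": null
    },
    {
      "row_id": "fast_food",
      "label": "Fast food",
      "kind": "frequency_range",
      "unit": "per_week",
      "cutoff_text": "0 times/week",
      "favorable": {"lo": 0.0, "lo_closed": true, "hi": 0.0, "hi_closed": true},
      "modifier": null
    },
    {
      "row_id": "salted_snacks",
      "label": "Salted snacks",
      "kind": "frequency_range",
      "unit": "per_week",
      "cutoff_text": "0 times/week",
      "favorable": {"lo": 0.0, "lo_closed": true, "hi": 0.0, "hi_closed": true},
      "modifier": null
    },
    {
      "row_id": "sodas",
      "label": "Sodas",
      "kind": "frequency_range",
      "unit": "per_week",
      "cutoff_text": "0 times/week",
      "favorable": {"lo": 0.0, "lo_closed": true, "hi": 0.0, "hi_closed": true},
      "modifier": null
    },
    {
      "row_id": "ready_to_eat",
      "label": "Ready-to-eat meals/Frozen food",
      "kind": "frequency_range",
      "unit": "per_week",
      "cutoff_text": "<=1 times/week",
      "favorable": {"lo": 0.0, "lo_closed": true, "hi": 1.0, "hi_closed": true},
      "modifier": null
    }
  ]
}
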