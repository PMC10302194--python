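{
  "name": "branded-food-gr-2022",
  "categories": {
    "Milk, milk product, or milk substitute": [
      "Milk",
      "Yogurt",
      "Cheese",
      "Milk substitute",
      "Milk cream",
      "Dairy dessert"
    ],
    "Fresh or processed eggs": [
      "Fresh or processed eggs",
      "Egg imitation"
    ],
    "Meat or related product": [
      "Poultry meat",
      "Preserved meat",
      "Sausage or similar meat",
      "Meat dish",
      "Meat analogue"
    ],
    "Seafood or related product": [
      "Seafood product"
    ],
    "Fat or oil": [
      "Vegetable fat or oil",
      "Margarine or lipid of mixed origins",
      "Butter or other animal fat"
    ],
    "Grain or grain product": [
      "Cereal or cereal-like milling products",
      "Rice or similar products",
      "Pasta and similar products",
      "Breakfast cereals",
      "Bread and similar products",
      "Fine bakery ware",
      "Savory cereal dish"
    ],
    "Nut, seed, or kernel": [
      "Nuts",
      "Seeds and kernels",
      "Nut or seed product"
    ],
    "Vegetable or vegetable product": [
      "Vegetable (excluding potato)",
      "Starchy root or potato",
      "Pulse or pulse product"
    ],
    "Fruit or fruit product": [
      "Processed fruit product"
    ],
    "Sugar or sugar product": [
      "Sugar, honey, or syrup",
      "Jam or marmalade",
      "Non-chocolate confectionery or other sugar product",
      "Chocolate or chocolate product"
    ],
    "Beverage": [
      "Juice or nectar",
      "Non-alcoholic beverage"
    ],
    "Miscellaneous food product": [
      "Spice, condiment, or other ingredient",
      "Prepared food product"
    ],
    "Ready meals": [
      "Ready to eat food",
      "Frozen, semi-ready meal"
    ]
  }
}
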