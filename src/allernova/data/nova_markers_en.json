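{
  "name": "nova4-markers-en",
  "marker_classes": {
    "sweeteners": {
      "terms": ["glucose syrup", "glucose-fructose syrup", "fructose syrup", "invert sugar syrup", "high fructose corn syrup", "sweetener", "sweeteners", "aspartame", "acesulfame k", "sucralose", "saccharin", "steviol glycosides", "sorbitol", "mannitol", "xylitol", "maltitol", "erythritol", "isoglucose"],
      "e_number_ranges": [[420, 421], [950, 969]]
    },
    "flavourings": {
      "terms": ["flavouring", "flavourings", "flavoring", "flavorings", "natural flavouring", "natural flavourings", "artificial flavouring", "aroma", "aromas", "flavour enhancer", "flavour enhancers", "flavor enhancer", "monosodium glutamate", "smoke flavouring"],
      "e_number_ranges": [[620, 640]]
    },
    "emulsifiers": {
      "terms": ["emulsifier", "emulsifiers", "lecithin", "lecithins", "soy lecithin", "sunflower lecithin", "mono- and diglycerides of fatty acids", "monoglycerides", "diglycerides", "polysorbate"],
      "e_number_ranges": [[322, 322], [471, 495]]
    },
    "thickeners": {
      "terms": ["thickener", "thickeners", "guar gum", "xanthan gum", "carrageenan", "locust bean gum", "gellan gum", "pectin", "pectins", "modified starch", "modified maize starch", "gelling agent", "stabiliser", "stabilizer", "stabilisers", "stabilizers"],
      "e_number_ranges": [[400, 418], [440, 466]]
    },
    "bulking_agents": {
      "terms": ["bulking agent", "bulking agents", "polydextrose", "maltodextrin", "maltodextrins"],
      "e_number_ranges": [[1200, 1200], [1400, 1452]]
    },
    "antioxidants": {
      "terms": ["antioxidant", "antioxidants", "ascorbic acid", "sodium ascorbate", "tocopherols", "butylated hydroxyanisole", "butylated hydroxytoluene", "erythorbic acid"],
      "e_number_ranges": [[300, 321]]
    },
    "protein_isolates": {
      "terms": ["protein isolate", "protein isolates", "protein concentrate", "protein concentrates", "soy protein isolate", "pea protein isolate", "pea protein", "whey protein concentrate", "milk protein concentrate", "hydrolysed protein", "hydrolyzed protein", "hydrolysed vegetable protein", "casein hydrolysate", "gluten hydrolysate"],
      "e_number_ranges": []
    },
    "vitamins_minerals": {
      "terms": ["vitamins", "added vitamins", "vitamins and minerals", "vitamin c", "vitamin d", "vitamin e", "vitamin b1", "vitamin b2", "vitamin b6", "vitamin b12", "thiamin", "riboflavin", "niacin", "folic acid", "pantothenic acid", "biotin", "ferric pyrophosphate", "zinc oxide", "calcium carbonate"],
      "e_number_ranges": []
    },
    "hydrolyzed_extruded": {
      "terms": ["hydrolysed", "hydrolyzed", "extruded", "puffed", "texturised", "texturized", "textured vegetable protein", "invert sugar"],
      "e_number_ranges": []
    },
    "extracts": {
      "terms": ["yeast extract", "malt extract", "barley malt extract", "meat extract", "rosemary extract", "paprika extract", "spice extract", "tea extract", "coffee extract"],
      "e_number_ranges": []
    }
  },
  "culinary_terms": ["salt", "sea salt", "iodised salt", "rock salt", "sugar", "cane sugar", "brown sugar", "icing sugar", "oil", "olive oil", "extra virgin olive oil", "sunflower oil", "vegetable oil", "rapeseed oil", "corn oil", "palm oil", "coconut oil", "starch", "corn starch", "potato starch", "rice starch", "butter", "lard", "animal fat", "honey"],
  "industrial_formulation_cues": ["ready to eat", "ready to heat", "ready meal", "instant", "imitation", "analogue", "analog", "substitute"],
  "subcategory_overrides": {}
}
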