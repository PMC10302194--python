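{
  "name": "eu-annex2-en",
  "allergens": {
    "gluten_cereals": {
      "canonical_terms": ["gluten", "wheat", "rye", "barley", "oats", "oat", "spelt", "kamut", "wheat flour", "whole wheat flour", "durum wheat semolina", "rye flour", "barley malt", "oat flakes", "cereals containing gluten"],
      "derivative_terms": ["semolina", "couscous", "bulgur", "malt", "malt extract", "breadcrumbs", "seitan", "spelt flour", "wheat starch", "wheat bran"],
      "exclusion_patterns": ["gluten-free", "gluten free", "free from gluten", "without gluten"]
    },
    "crustaceans": {
      "canonical_terms": ["crustaceans", "crustacean", "shrimp", "shrimps", "prawn", "prawns", "crab", "lobster", "crayfish"],
      "derivative_terms": ["shrimp extract", "krill"],
      "exclusion_patterns": []
    },
    "eggs": {
      "canonical_terms": ["egg", "eggs", "egg yolk", "egg white", "whole egg", "egg powder"],
      "derivative_terms": ["albumin", "albumen", "ovalbumin", "lysozyme"],
      "exclusion_patterns": ["egg-free", "egg free", "free from egg", "without egg"]
    },
    "fish": {
      "canonical_terms": ["fish", "cod", "salmon", "tuna", "anchovy", "anchovies", "sardine", "sardines", "trout", "mackerel", "herring"],
      "derivative_terms": ["fish gelatine", "fish oil", "fish sauce", "surimi"],
      "exclusion_patterns": []
    },
    "peanuts": {
      "canonical_terms": ["peanut", "peanuts", "groundnut", "groundnuts"],
      "derivative_terms": ["peanut oil", "peanut flour", "arachis oil"],
      "exclusion_patterns": ["peanut-free", "peanut free"]
    },
    "soybeans": {
      "canonical_terms": ["soy", "soya", "soybean", "soybeans", "soya bean", "soya beans"],
      "derivative_terms": ["tofu", "soya flour", "soy flour", "soy protein", "soya protein", "soy sauce", "edamame", "tempeh", "miso"],
      "exclusion_patterns": ["soy-free", "soy free", "soya-free"]
    },
    "milk": {
      "canonical_terms": ["milk", "whole milk", "skimmed milk", "semi-skimmed milk", "milk powder", "skimmed milk powder", "milk solids", "milk proteins"],
      "derivative_terms": ["whey", "whey powder", "whey protein", "casein", "caseinate", "caseinates", "lactose", "butter", "butterfat", "buttermilk", "cream", "yogurt", "yoghurt", "cheese", "ghee", "curd"],
      "exclusion_patterns": ["milk-free", "milk free", "dairy-free", "dairy free", "lactose-free milk substitute", "cocoa butter", "shea butter", "peanut butter", "almond butter", "nut butter", "cream of tartar"]
    },
    "tree_nuts": {
      "canonical_terms": ["nuts", "nut", "tree nuts", "almond", "almonds", "hazelnut", "hazelnuts", "walnut", "walnuts", "cashew", "cashews", "pecan", "pecans", "pistachio", "pistachios", "macadamia", "brazil nut", "brazil nuts"],
      "derivative_terms": ["almond flour", "hazelnut paste", "praline", "marzipan", "nut butter", "almond butter"],
      "exclusion_patterns": ["nut-free", "nut free"]
    },
    "celery": {
      "canonical_terms": ["celery", "celeriac"],
      "derivative_terms": ["celery salt", "celery seed", "celery extract"],
      "exclusion_patterns": []
    },
    "mustard": {
      "canonical_terms": ["mustard"],
      "derivative_terms": ["mustard seed", "mustard seeds", "mustard flour", "dijon mustard"],
      "exclusion_patterns": []
    },
    "sesame": {
      "canonical_terms": ["sesame", "sesame seed", "sesame seeds"],
      "derivative_terms": ["tahini", "sesame oil", "sesame paste"],
      "exclusion_patterns": []
    },
    "sulphites": {
      "canonical_terms": ["sulphites", "sulfites", "sulphite", "sulfite", "sulphur dioxide", "sulfur dioxide"],
      "derivative_terms": ["sodium metabisulphite", "sodium metabisulfite", "potassium metabisulphite", "sodium sulphite", "sodium bisulphite", "calcium sulphite"],
      "e_number_ranges": [[220, 228]],
      "exclusion_patterns": []
    },
    "lupin": {
      "canonical_terms": ["lupin", "lupine"],
      "derivative_terms": ["lupin flour", "lupin protein"],
      "exclusion_patterns": []
    },
    "mollusks": {
      "canonical_terms": ["mollusks", "molluscs", "mollusc", "mollusk", "mussel", "mussels", "oyster", "oysters", "squid", "octopus", "clam", "clams", "scallop", "scallops", "snail", "snails", "cuttlefish"],
      "derivative_terms": ["oyster sauce", "squid ink"],
      "exclusion_patterns": []
    }
  },
  "trigger_phrases": [
    "may contain traces of",
    "may contain trace of",
    "may contain",
    "manufactured in a facility that also processed",
    "manufactured in a facility that also processes",
    "produced in a facility that also processes",
    "produced in a facility that also handles",
    "made in a factory that also handles",
    "may be present",
    "traces of"
  ],
  "contains_statement_phrases": [
    "contains",
    "contains:"
  ]
}
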