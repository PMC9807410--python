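"""Transcription of the MHLW stockpile Simulator's printed food-product lists.

The Simulator's pull-down food list is split into "staple foods" (four
groups, energy carriers) and "main and side dishes" (five groups, the
protein/vitamin carriers).  Item names are kept verbatim, including
transliterated Japanese terms.  The source prints item lists for the four
staple groups and for three of the five main/side groups; "Milk and juice"
and "Seasonings" are named as groups but no item list is printed for them,
so they appear here as empty categories.

Two distinct items print the same name "Rice flour" (one in the flour
group, one in the noodle group); ids generated from these names are
disambiguated with a numeric suffix.

Only names and group membership are transcribed.  Nutrient compositions,
pack sizes and stockpilability flags are NOT printed in the source; the
flags attached in :func:`nutristock.reference_data.bundled_catalog` are
synthetic per-category defaults for testing and filtering demos.
"""

STAPLE_CATEGORIES = (
    "Rice and the like",
    "Wheat flour, rice flour, rice cakes",
    "Dried noodles, instant noodles, cup noodles",
    "Dried bread, cookies, and the like",
)

MAIN_SIDE_CATEGORIES = (
    "Pouched, sterilized food",
    "Canned food",
    "Dried food",
    "Milk and juice",
    "Seasonings",
)

BUNDLED_ITEMS: dict[str, tuple[str, ...]] = {
    "Rice and the like": (
        "Alpha rice",
        "Porridge",
        "Brown rice",
        "Half-polished rice",
        "70% polished rice",
        "Polished, white, ordinary rice",
        "Polished, white, glutinous rice",
        "Polished Indica rice",
        "Polished whole rice with germ",
        "Germinated brown rice",
    ),
    "Wheat flour, rice flour, rice cakes": (
        "Wheat flour",
        "Premix flour for okonomiyaki",
        "Premix pancake flour",
        "Wheat germ",
        "Rice cakes",
        "Top-grade rice flour made from non-glutinous rice",
        "Brown rice flour",
        "Rice flour",
        "Glutinous rice powder",
        "Rice bran",
    ),
    "Dried noodles, instant noodles, cup noodles": (
        "Instant Chinese noodles",
        "Chinese-style instant cup noodles",
        "Chinese-style instant cup Yaki-soba noodles",
        "Japanese-style instant cup noodles",
        "Barley, dried barley noodles",
        "Dried udon noodles",
        "Dried Somen/Hiyamugi noodles",
        "Dried Chinese noodles",
        "Dried Okinawa soba noodles",
        "Dried macaroni, spaghetti",
        "Soba noodles, dried soba noodles",
        "Rice flour",
        "Rice noodles",
    ),
    "Dried bread, cookies, and the like": (
        "Hardtack",
        "Canned bread",
        "Cookies",
        "Cereal",
        "Sweet red bean jelly (Youkan)",
        "Balanced, nutritional food",
    ),
    "Pouched, sterilized food": (
        "Pouched beef curry",
        "Pouched beef stew",
        "Corn cream soup powder",
        "Pouched corn cream soup",
        "Curry roux",
        "Hashed beef roux",
        "Salmon flake and green tea rice seasoning mix",
        "Instant clear soup",
        "Rice dried topping powder",
    ),
    "Canned food": (
        "Canned sardines",
        "Canned tuna",
        "Canned salmon, trout",
        "Canned mackerel",
        "Canned Pacific saury",
        "Canned tuna in water",
        "Canned tuna in oil",
        "Canned clams",
        "Canned boiled abalone in water",
        "Canned smoked oyster in oil",
        "Canned bamboo shoots (seasoned)",
        "Canned scallops in water",
        "Canned boiled snow crab in water",
        "Canned boiled king crab in water",
        "Canned seasoned squid and the like",
        "Canned corned beef",
        "Canned grilled chicken",
        "Canned quail eggs in water",
        "Canned whole eggs in water",
        "Canned boiled yellow soybeans",
        "Canned boiled adzuki beans",
        "Canned boiled asparagus in water",
        "Canned boiled green peas in water",
        "Canned bamboo shoots in water",
        "Canned sweet corn",
        "Canned whole tomatoes",
        "Canned boiled Nameko mushrooms in water",
        "Canned boiled mushroom in water",
        "Canned bee larva",
    ),
    "Dried food": (
        "Dried gourds",
        "Dried taro stems",
        "Dried osmund",
        "Dried daikon strips",
        "Dried Chinese chili peppers",
        "Dried bracken",
        "Dried wood ear mushroom",
        "Dried Shitake mushrooms",
        "Dried Maitake mushrooms",
        "Natural-dried sea lettuce",
        "Dried steamed Arame seaweed",
        "Natural-dried Nori",
        "Natural-dried kelp",
        "Flaked kelp",
        "Natural-dried red algae",
        "Stainless-kettle dried starry elm",
        "Iron-kettle dried starry elm",
        "Natural-dried Monostroma nitidum",
        "Natural-dried Funori seaweed",
        "Natural-dried Coontail",
        "Natural-dried Wakame seaweed",
        "Natural-dried Wakame seaweed in water",
        "Dried Wakame stems",
        "Dried boiled infant Pacific sand eel",
        "Dried whole Urume sardines",
        "Small, boiled–dried Katakuchi sardines",
        "Dried whole Japanese pilchard",
        "Dried bonito flakes",
        "Dried flatfish",
        "Dried, seasoned silver-stripe round herring",
        "(sardines and the like) Dried blue mackerel flakes",
        "(sardines and the like) Sundried sliced mackerel",
        "Sundried, sliced Pacific saury",
        "Sundried, sliced, Mirin-seasoned Pacific saury",
        "Dried Pacific cod",
        "Sundried, sliced-open herrings",
        "Dried herring roes",
        "Dried abalone",
        "Boiled–dried scallop adductors",
        "Sakura shrimps",
        "Dried shrimps",
        "Dried squid",
        "Shredded dried squid",
        "(squid and the like) Smoked squid",
        "Dried whole eggs",
        "Dried egg yolk",
        "Dried egg white",
    ),
    "Milk and juice": (),
    "Seasonings": (),
}

# Synthetic per-category stockpilability defaults (not printed in the
# source lists; chosen so filtering behaves the way practitioners
# described: dried goods and raw flours/noodles/rice need cooking).
CATEGORY_REQUIRES_COOKING = {
    "Rice and the like": True,
    "Wheat flour, rice flour, rice cakes": True,
    "Dried noodles, instant noodles, cup noodles": True,
    "Dried bread, cookies, and the like": False,
    "Pouched, sterilized food": False,
    "Canned food": False,
    "Dried food": True,
    "Milk and juice": False,
    "Seasonings": False,
}

# Ready-to-eat exceptions within cooking-required categories.
READY_TO_EAT = frozenset({"Alpha rice", "Porridge"})

# Wheat-allergy flag: synthetic name-based heuristic over the transcribed
# lists (the source only notes that rice items matter for wheat allergies).
_WHEAT_TOKENS = (
    "Wheat",
    "udon",
    "Somen",
    "Hiyamugi",
    "macaroni",
    "spaghetti",
    "okonomiyaki",
    "pancake",
    "Hardtack",
    "bread",
    "Cookies",
    "Cereal",
    "soba",  # soba noodles are typically wheat blends
)
_WHEAT_EXEMPT_PREFIXES = ("Rice", "Barley")


def contains_wheat(name: str) -> bool:
    if name.startswith(_WHEAT_EXEMPT_PREFIXES):
        return False
    low = name.lower()
    if "chinese noodles" in low or "cup noodles" in low or "yaki-soba" in low:
        return True
    return any(tok.lower() in low for tok in _WHEAT_TOKENS)
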