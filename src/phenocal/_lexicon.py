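"""Multilingual phrase pools and stopwords for herbarium label text.

Herbarium field notes in the neotropics mix Spanish, Portuguese and
English.  These pools drive both the synthetic label generator and the
default stopword filtering of the classifier; both are configurable.
"""

# Phrases a collector writes when the specimen is in flower.
FLOWERING_PHRASES = (
    "flores blancas",
    "flores amarillas",
    "flores moradas",
    "flores rosadas vistosas",
    "en flor",
    "flor blanca con aroma dulce",
    "inflorescencia con flores abiertas",
    "com flores brancas",
    "com flores amarelas",
    "flores cremes",
    "flowers white",
    "flowers yellow fragrant",
    "in flower",
    "flowering throughout the crown",
    "corola blanca estambres amarillos",
)

# Phrases indicating a sterile or fruiting specimen (not flowering).
NON_FLOWERING_PHRASES = (
    "estéril",
    "esteril sin estructuras reproductivas",
    "frutos verdes",
    "frutos maduros rojos",
    "con frutos inmaduros",
    "com frutos verdes",
    "infrutescencia pendular",
    "sterile",
    "fruits green",
    "fruits ripe purple",
    "in fruit",
    "only leaves collected",
    "somente folhas",
)

# Habitat and collector chatter, common to both classes.
NEUTRAL_PHRASES = (
    "árbol de 12 m",
    "arbusto de 3 m en borde de bosque",
    "bosque nublado primario",
    "orilla de quebrada",
    "tree 8 m tall bark smooth",
    "colectado en ladera pendiente fuerte",
    "mata de terra firme",
    "hojas coriáceas verde oscuro",
    "suelo arcilloso húmedo",
    "canopy emergent",
    "floresta ombrófila densa",
    "pastizal abandonado cerca del río",
)

# Small trilingual stopword list (articles, prepositions, conjunctions).
STOPWORDS = frozenset(
    """
    de la el los las un una unas unos y o en con del al por para sobre
    da do das dos na no nas nos em com um uma para por sem
    the of and or in on at with to for from by near
    """.split()
)
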