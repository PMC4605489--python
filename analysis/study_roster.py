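"""The study roster: 27 craniometric series with published sample sizes.

Sample sizes, male/female counts, missing-value percentages and regional
affiliations of the series used in the early-vs-recent South American
comparison.  These census numbers are published metadata; the measurement
values attached to them by ``01_simulate_panel.py`` are SYNTHETIC.
"""

# (series, region, n, males, females, pct_missing)
ROSTER = [
    ("Lagoa Santa", "Early America", 29, 18, 11, 16.94),
    ("Paleo Colombia", "Early America", 14, 6, 8, 6.52),
    ("Peru", "South America", 110, 55, 55, 0.0),
    ("Botocudo", "South America", 32, 16, 16, 1.90),
    ("Archaic Colombia", "South America", 33, 12, 21, 11.86),
    ("Tapera", "South America", 47, 26, 21, 5.28),
    ("Cabeçuda", "South America", 19, 12, 7, 13.50),
    ("Tupi-Guarani", "South America", 23, 14, 9, 2.65),
    ("Arikara", "North America", 69, 42, 27, 0.0),
    ("Santa Cruz", "North America", 102, 51, 51, 0.0),
    ("Eskimo", "North America", 108, 53, 55, 0.0),
    ("North Japan", "East Asia", 87, 55, 32, 0.0),
    ("South Japan", "East Asia", 91, 50, 41, 0.0),
    ("Hainan", "East Asia", 83, 45, 38, 0.0),
    ("Buriat", "East Asia", 109, 55, 54, 0.0),
    ("Australia", "Australo-Melanesia", 101, 52, 49, 0.0),
    ("Tasmania", "Australo-Melanesia", 87, 45, 42, 0.0),
    ("Tolai", "Australo-Melanesia", 110, 56, 54, 0.0),
    ("Berg", "Europe", 109, 56, 53, 0.0),
    ("Norse", "Europe", 110, 55, 55, 0.0),
    ("Zalavar", "Europe", 98, 53, 45, 0.0),
    ("Zulu", "Sub-Saharan Africa", 101, 55, 46, 0.0),
    ("Dogon", "Sub-Saharan Africa", 99, 47, 52, 0.0),
    ("Teita", "Sub-Saharan Africa", 83, 33, 50, 0.0),
    ("Easter Island", "Polynesia", 86, 49, 37, 0.0),
    ("Mokapu", "Polynesia", 100, 51, 49, 0.0),
    ("Moriori", "Polynesia", 108, 57, 51, 0.0),
]

#: worldwide between-series apportionment used to diverge the synthetic means
WORLD_FST = 0.276
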