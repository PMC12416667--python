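"""Per-site P450 diversity statistics from published count data.

The diversity percentage, 100 * families / P450s, measures how spread a
site's P450 complement is across families: 100% means every sequence is the
sole representative of its family; low values mean a few families dominate.
"""

from cypminer import diversity_percentage, dominant_families

# (site, extreme condition, n_p450, n_families) as published for six
# extreme sites in Türkiye (hydrothermal springs, hypersaline lakes, and an
# acid-mine drainage site)
SITES = [
    ("Armutlu", "hydrothermal", 3, 3),
    ("Balya", "acidic", 92, 37),
    ("Gomec", "hypersaline", 57, 27),
    ("Hisaralan", "hydrothermal", 49, 23),
    ("Lake Acigol", "hypersaline", 31, 16),
    ("Tuz Golu", "hypersaline", 79, 13),
]

print(f"{'site':<12} {'condition':<13} {'P450s':>5} {'families':>8} {'diversity %':>11}")
for site, condition, n_p450, n_families in SITES:
    pct = diversity_percentage(n_p450, n_families)
    print(f"{site:<12} {condition:<13} {n_p450:>5} {n_families:>8} {pct:>11}")

# Tuz Golu has the second-most P450s but by far the lowest diversity:
# a handful of families (led by CYP174) dominate the hypersaline lake.
counts = {"CYP174": 28, "CYP1002": 9, "CYP109": 6}
print("\nTuz Golu dominant families:", dominant_families(counts))
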