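"""Scanning protein sequences for the P450 heme-binding motif.

The consensus motif F(x)n G/A (x)m C x G (n in 2..5, m in 3..6) contains the
axial cysteine that coordinates the heme iron — its presence is the
structural criterion separating genuine P450s from look-alikes. Windows
matching everything except the cysteine are reported as near-misses, since
natural Cys->Tyr substitutions at this position are known.
"""

from cypminer import find_heme_motifs

examples = {
    "typical spacers (n=2, m=3)": "AASLDERTFGAGSHICLGQHLA",
    "widest spacers (n=5, m=6)": "AAFAAAAAGAAAAAACLGQHLA",
    "Cys->Tyr near-miss": "AASLDERTFGAGSHIYLGQHLA",
    "no motif at all": "AASLDERTAGAGSHILLGQHLA",
}

for label, seq in examples.items():
    hits = find_heme_motifs(seq)
    canonical = [h for h in hits if h.canonical]
    near = [h for h in hits if not h.canonical]
    print(f"{label}:")
    for h in canonical:
        print(f"  canonical {h.matched!r} at {h.start} (n={h.n}, m={h.m}, axial C)")
    for h in near:
        print(f"  near-miss {h.matched!r} at {h.start} (axial {h.axial}, not C)")
    if not hits:
        print("  nothing found")

# Only sequences with at least one canonical hit survive the filter
# cascade; near-misses are surfaced so unusual heme ligation can be studied.
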