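"""Compute Protection Equality for a small hand-made feature table.

Six coral-reef "countries" with very different total areas and protection
levels; prints raw and corrected PE for both metric variants.
"""

from pequal import FeatureTable, pe_fixed, pe_proportional

# (id, total area km2, protected km2)
table = FeatureTable(
    [
        ("Alpha", 5000.0, 1500.0),
        ("Bravo", 22000.0, 1200.0),
        ("Charlie", 900.0, 30.0),
        ("Delta", 14000.0, 4100.0),
        ("Echo", 2500.0, 80.0),
        ("Foxtrot", 40000.0, 6400.0),
    ]
)

rp = pe_proportional(table)
rf = pe_fixed(table)
print(f"N = {table.n} features, total area {table.total_area:.0f} km2, "
      f"protected {table.total_protected:.0f} km2")
print(f"proportional PE: raw {rp.raw:.3f}, corrected {rp.corrected:.3f}")
print(f"fixed-area  PE: raw {rf.raw:.3f}, corrected {rf.corrected:.3f}")
print()
print("Corrected values near 1 would mean every feature is protected equally")
print("(as a fraction of its area for PE_p, in absolute km2 for PE_f);")
print("values near 0 mean protection is concentrated in a few features.")
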