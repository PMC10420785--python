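"""Water-use efficiency and fruit quality from treatment tables.

Computes WUE and the taste index from per-treatment means, plus the
percent change of each treatment against the bare control.
"""

from soilmulch import FruitQuality, PlantOutcome, percent_change, taste_index, wue

plants = {
    "bare": PlantOutcome("bare", biomass=1112, yield_=801, water=6.2),
    "newspaper": PlantOutcome("newspaper", biomass=2031, yield_=1456, water=8.6),
    "bran": PlantOutcome("bran", biomass=1447, yield_=939, water=5.0),
    "grass": PlantOutcome("grass", biomass=1311, yield_=890, water=6.0),
}
print("treatment   WUE_b  WUE_y  (g per mm of water)")
for name, outcome in plants.items():
    res = wue(outcome)
    print(f"{name:10} {res.wue_b:6.0f} {res.wue_y:6.0f}")

bare = plants["bare"]
print("\npercent change vs bare control:")
for name in ("newspaper", "bran", "grass"):
    o = plants[name]
    print(f"{name:10} biomass {percent_change(o.biomass, bare.biomass):+6.1f} %   "
          f"yield {percent_change(o.yield_, bare.yield_):+6.1f} %")

print("\ntaste index (sugar/(20*acid) + acid):")
for name, sugar, acid in (("bare", 9.3, 0.87), ("newspaper", 7.6, 0.81)):
    res = taste_index(FruitQuality(name, sugar=sugar, acid=acid))
    print(f"{name:10} {res.index:.2f}")
# WUE ranks bran best (least water per gram); the taste index drops
# under the reflective mulch because its fruit is less sweet.
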