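"""Which parental genotype pairs let us deduce the transmitted origin?

Classifies three constellations at one marker where 200/220 are
Australian-origin lengths and 210/230 Timor-origin, then deduces
transmissions for concrete offspring.
"""

from meiodrive.ancestry import (
    OriginRegistry,
    classify_pair,
    deduce_transmission,
)

registry = OriginRegistry(origins={
    ("m", 200): "AUS", ("m", 220): "AUS",
    ("m", 210): "TIM", ("m", 230): "TIM",
})

cases = [
    ("disjoint partner", (200, 210), (220, 230)),
    ("partner shares one length", (200, 210), (210, 220)),
    ("AB x AB (same two lengths)", (200, 210), (200, 210)),
]
for name, dam, sire in cases:
    pcs = classify_pair(dam, sire, "m", registry)
    for pc in pcs:
        print(f"{name:28s} focal={pc.focal:4s} -> {pc.status}")

print()
pc = classify_pair((200, 210), (200, 210), "m", registry)[0]
for off in [(200, 200), (210, 210), (200, 210)]:
    print(f"AB x AB offspring {off}: focal dam transmitted "
          f"{deduce_transmission(pc, off)!r}")

print("\n1 = Australian allele, 0 = Timor allele.  The heterozygous AB x AB")
print("offspring is 'ambiguous' and is never counted; the homozygotes pin")
print("down the transmitted origin of *both* parents at once.")
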