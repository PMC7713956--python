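"""Simulate the backcross design with a weak female centromeric drive
and recover the drive parameter k from the genotypes alone.

A drive value d = 0.475 means the Australian-origin centromere enters
the oocyte in 47.5% of female meioses I — a 2.5-point bias toward the
Timor allele, the size of effect the pipeline is built to detect.
"""

from meiodrive import CrossConfig, simulate_cross, ancestry, anomaly, inference

cfg = CrossConfig(rng_seed=42, drive={("all", "F", "MI_centromere"): 0.475})
ds, truth = simulate_cross(cfg)

ds = ancestry.apply_w_coding(ds)
excl = anomaly.exclusion_set(anomaly.detect_anomalies(ds), ds)
ds, null_calls = ancestry.infer_null_alleles(ds)
registry = ancestry.build_origin_registry(ds)
result = ancestry.count_transmissions(ds, registry,
                                      excluded_offspring_chromosomes=excl)
records = result.records

print(f"{result.ledger['total']} transmissions determined, "
      f"{result.ledger['informative']} informative "
      f"({result.ledger['informative_percent']:.1f}%), "
      f"{len(null_calls)} null alleles inferred")

p0 = inference.background_rate(records, mode="raw")
print(f"background rate (pooled male k): {p0:.4f}")

for label, sub in (
    ("female centromeric",
     records[(records.parent_sex == "F")
             & (records.position_class == "centromeric")]),
    ("female distal",
     records[(records.parent_sex == "F") & (records.position_class == "distal")]),
    ("male (all markers)", records[records.parent_sex == "M"]),
):
    est = inference.estimate_k(int(sub.transmitted.sum()), len(sub), p0=p0)
    print(f"{label:22s} k = {est.k:.4f} "
          f"(95% CI {est.ci95[0]:.4f}-{est.ci95[1]:.4f}), "
          f"p = {est.p_binomial:.2g} vs background")

print("\nThe female centromeric estimate should sit near the injected 0.475")
print("(slightly above it, because a few centromeric markers lie up to 27 cM")
print("from the centromere); male and distal estimates stay near 0.5 —")
print("drive acts only in female meiosis and is unlinked from 50-cM markers.")
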