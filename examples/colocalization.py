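"""Colocalization under shared vs distinct causal variants.

Simulates one region where protein and disease share a causal variant
(H4) and one where they have different ones (H3), then compares the
posterior hypothesis probabilities at the primary and sensitivity p12
priors.
"""

from pqtlmr.coloc import sensitivity
from pqtlmr.gwas_io import harmonize
from pqtlmr.synthetic import ScenarioConfig, simulate_region

for scen in ("H4", "H3"):
    study = simulate_region(
        ScenarioConfig(causal_scenario=scen, b_protein=0.2, theta=0.3, seed=5),
        region_tag=scen)
    pairs, _ = harmonize(study.protein_stats, study.disease_stats)
    results = sensitivity(pairs, [1e-5, 5e-6])
    primary = results[0]
    print(f"\nscenario {scen}: protein causal at {study.truth.causal_snp_protein}, "
          f"disease at {study.truth.causal_snp_disease}")
    print("  " + "  ".join(f"{h.upper()}={v:.3f}" for h, v in primary.as_dict().items()))
    print(f"  PPH4 at p12 1e-5 / 5e-6: "
          f"{results[0].pph4:.3f} / {results[1].pph4:.3f} -> {primary.label}")

print("\nPPH4 near 1 indicates a shared causal variant (colocalization); "
      "under distinct variants the mass moves to PPH3.")
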