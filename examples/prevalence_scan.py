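"""Tumor-type prevalence of hotspots.

After detection, each (hotspot, tumor type) pair is tested with a
two-sided Fisher exact test on carriers-in-type vs carriers-elsewhere;
pairs significant at BH q < 0.01 are "prevalent", and a hotspot whose
carriers all sit in one type is "exclusive" to it.
"""

from hotspots import (
    PlantedHotspot,
    SimulationConfig,
    call_hotspots_all_types,
    multiplicity_summary,
    prevalence_scan,
    simulate_dataset,
)
from hotspots.prevalence import results_to_frame

config = SimulationConfig(
    seed=23,
    tumor_types=["colorectal", "breast", "lung"],
    n_samples={"colorectal": 120, "breast": 120, "lung": 360},
    genes=[("GENE1", 300), ("GENE2", 400)],
    background_rates={
        (t, g, "missense_NoCpG_CGts"): 8.0
        for t in ("colorectal", "breast", "lung")
        for g in ("GENE1", "GENE2")
    },
    planted_hotspots=[
        # same site planted in two types, absent from lung
        PlantedHotspot("colorectal", "GENE1", 150, "missense_NoCpG_CGts", 15),
        PlantedHotspot("breast", "GENE1", 150, "missense_NoCpG_CGts", 14),
        # a site private to breast
        PlantedHotspot("breast", "GENE2", 77, "missense_NoCpG_CGts", 8),
    ],
)
dataset = simulate_dataset(config, apply_hypermutation_filter=False)
calls = call_hotspots_all_types(dataset, alpha=0.001)
results = prevalence_scan(calls, dataset, alpha=0.01)

print(results_to_frame(results).to_string(index=False))
print("\nHotspot multiplicity (number of tumor types in which a hotspot "
      "is prevalent -> number of hotspots):")
print(multiplicity_summary(results))
print("\nGENE1:150 should be prevalent in both colorectal and breast "
      "(multiplicity 2) while GENE2:77 is prevalent in breast only; "
      "'exclusive' marks hotspots whose carriers are confined to a single "
      "tumor type.")
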