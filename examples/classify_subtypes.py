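"""Classify mutations into the 20 consequence-by-context subtypes.

Every SNV is labeled by its protein-level consequence (missense, nonsense,
silent) crossed with its strand-symmetric sequence context: A:T
transition/transversion, and C:G transition/transversion split by whether
the pyrimidine sits in a CpG dinucleotide. Insertions and deletions form
two further subtypes. The classification drives the subtype-specific
backgrounds used by the detector.
"""

from hotspots import (
    SimulationConfig,
    classify_context,
    simulate_dataset,
    subtype_count_matrix,
)

print("Single-base contexts (ref, alt, left flank, right flank):")
for ref, alt, left, right in [
    ("C", "T", "A", "G"),   # C>T with G to the right: CpG transition
    ("C", "T", "A", "A"),   # C>T outside CpG
    ("G", "A", "C", "T"),   # G>A = C>T on the other strand, CpG on left
    ("A", "G", "T", "T"),   # A:T transition
    ("A", "T", "C", "C"),   # A:T transversion
    ("C", "A", "T", "T"),   # C:G transversion outside CpG
]:
    ctx = classify_context(ref, alt, left, right)
    print(f"  {left}[{ref}>{alt}]{right}  ->  {ctx.value}")

config = SimulationConfig(
    seed=5,
    tumor_types=["colorectal"],
    n_samples={"colorectal": 80},
    genes=[("GENE1", 300)],
    background_rates={
        ("colorectal", "GENE1", "missense_CpG_CGts"): 25,
        ("colorectal", "GENE1", "silent_ATts"): 10,
        ("colorectal", "GENE1", "deletion"): 5,
    },
)
dataset = simulate_dataset(config)
counts = subtype_count_matrix(dataset, "colorectal")
nonzero = counts.loc[:, (counts != 0).any()]
print("\nGene x subtype counts for the simulated colorectal cohort "
      "(nonzero columns):")
print(nonzero.to_string())
print("\nThe count matrix is the input to background estimation: each "
      "nonzero column contributes one Poisson background rate per gene.")
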