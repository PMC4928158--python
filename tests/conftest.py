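import pytest

from hotspots import PlantedHotspot, SimulationConfig, simulate_dataset


def small_cohort_config(seed: int = 11, planted: bool = True) -> SimulationConfig:
    """A two-tumor-type cohort small enough for fast tests."""
    hotspots = []
    if planted:
        hotspots = [
            PlantedHotspot("colorectal", "GENE1", 150, "missense_NoCpG_CGts", 8),
            PlantedHotspot("breast", "GENE3", 50, "insertion", 6),
            PlantedHotspot("colorectal", "GENE2", 77, "deletion", 7),
        ]
    return SimulationConfig(
        seed=seed,
        tumor_types=["colorectal", "breast"],
        n_samples={"colorectal": 120, "breast": 150},
        genes=[("GENE1", 300), ("GENE2", 500), ("GENE3", 250)],
        background_rates={
            ("colorectal", "GENE1", "missense_NoCpG_CGts"): 20,
            ("colorectal", "GENE1", "missense_ATts"): 8,
            ("colorectal", "GENE2", "deletion"): 6,
            ("colorectal", "GENE2", "silent_CpG_CGts"): 10,
            ("breast", "GENE1", "missense_NoCpG_CGtv"): 15,
            ("breast", "GENE3", "insertion"): 4,
        },
        planted_hotspots=hotspots,
    )


@pytest.fixture(scope="session")
def planted_dataset():
    # no hyper-mutated samples are planted, so the outlier filter stays off:
    # at these sparse per-sample counts mu + 2*sigma sits below 2 mutations
    # and would discard legitimate hotspot carriers
    return simulate_dataset(small_cohort_config(seed=11),
                            apply_hypermutation_filter=False)


@pytest.fixture(scope="session")
def planted_calls(planted_dataset):
    from hotspots import call_hotspots_all_types

    return call_hotspots_all_types(planted_dataset)
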