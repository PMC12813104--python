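import numpy as np
import pandas as pd
import pytest

from kitbench import (
    KitSpec,
    OtuTable,
    SpeciesSpec,
    TaxonomyTable,
    default_kits,
    default_species,
    generate_benchmark_dataset,
)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-world dataset shared by read-only tests."""
    return generate_benchmark_dataset(
        default_species(), default_kits(), n_replicates=3, depth=50_000, seed=11
    )


@pytest.fixture
def tiny_table():
    """A hand-checkable 3-sample x 4-OTU table."""
    return OtuTable.from_counts(
        [[40, 60, 0, 0], [10, 10, 10, 10], [0, 0, 5, 5]],
        sample_ids=["s1", "s2", "s3"],
        otu_ids=["chloroA", "bactB", "bactC", "bactD"],
    )


@pytest.fixture
def tiny_taxonomy():
    return TaxonomyTable.from_records(
        {
            "chloroA": ("Bacteria", "Cyanobacteria", "Cyanobacteriia", "Chloroplast", "", ""),
            "bactB": ("Bacteria", "Bacteroidota", "Bacteroidia", "Flavobacteriales", "Flavobacteriaceae", "Maribacter"),
            "bactC": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae", "Sulfitobacter"),
            "bactD": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Alteromonadales", "", ""),
        }
    )


def dominant_world():
    """A planted world where kit 'Star' strictly dominates every criterion.

    Star: highest template (yield), no bias or dropout (top Shannon and
    reproducibility), negligible contaminant load, no PCR dilution, best
    DIN, simplest protocol, cheapest. The other five kits are clearly worse
    everywhere except (possibly) chloroplast content, which is species- not
    kit-determined.
    """
    species = [
        SpeciesSpec("algaA", n_otus=40, chloroplast_fraction=0.30, n_chloroplast_otus=3),
        SpeciesSpec("algaB", n_otus=40, chloroplast_fraction=0.10, n_chloroplast_otus=2),
    ]
    kits = [
        KitSpec("Star", capture_bias_sd=0.0, dropout_rate=0.0,
                contaminant_load_ng=0.01, mean_template_ng=100.0, dilution_factor=1,
                simplicity=1, cost_per_sample=3.0, kitome_read_factor=0.2, din_mean=9.0),
    ]
    for i, (template, din, cost) in enumerate(
        [(10.0, 5.0, 5.0), (8.0, 4.5, 6.0), (6.0, 4.0, 7.0), (4.0, 3.5, 8.0), (2.0, 3.0, 9.0)]
    ):
        kits.append(
            KitSpec(
                f"Dull{i}", capture_bias_sd=1.2, dropout_rate=0.35,
                contaminant_load_ng=5.0, mean_template_ng=template,
                dilution_factor=10, simplicity=3, cost_per_sample=cost,
                kitome_read_factor=0.8, din_mean=din,
            )
        )
    return species, kits
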