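import logging

import numpy as np
import pytest

from orbpool.core import AtomicSystem, ElectronicReference, LabeledDataset
from orbpool.descriptors import DescriptorConfig
from orbpool.tightbinding import GeneratorConfig, TBParams, generate_dataset

logging.getLogger("orbpool").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tb_params():
    return TBParams()


@pytest.fixture(scope="session")
def small_dataset(tb_params):
    """150 default synthetic molecules (fixed seed)."""
    return generate_dataset(GeneratorConfig(n_molecules=150, seed=42), tb_params)


@pytest.fixture(scope="session")
def dataset_channels(small_dataset):
    seen = set()
    for system, _ in small_dataset:
        seen.update(system.elements)
    return tuple(sorted(seen))


@pytest.fixture(scope="session")
def small_descriptor(dataset_channels):
    return DescriptorConfig(
        element_channels=dataset_channels, cutoff_radius=4.0, n_centers=8
    )


def random_dataset(rng, n_records=5, mode="max", with_l=True):
    """Small random labeled dataset for I/O round-trip tests."""
    records = []
    tags = []
    for k in range(n_records):
        n = int(rng.integers(1, 7))
        elements = [str(rng.choice(["C", "O", "H", "R07"])) for _ in range(n)]
        coords = rng.normal(0, 3.0, (n, 3))
        frag = rng.integers(0, 2, n) if rng.random() < 0.5 else None
        l = None
        L = None
        if with_l and n >= 2:
            raw = rng.random(n) + 0.05
            l = raw / raw.sum()
            L = float((n * float(l @ l) - 1) / (n - 1))
        records.append(
            (
                AtomicSystem(elements, coords, system_id=f"sys-{k}",
                             fragment_labels=frag),
                ElectronicReference(
                    target_energy=float(rng.normal(-7, 2)),
                    mode=mode,
                    localization_fractions=l,
                    localization_index=L,
                ),
            )
        )
        tags.append(str(rng.choice(["train", "val", "test"])))
    return LabeledDataset(records=records, split_tags=tags, provenance="random")
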