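import numpy as np
import pytest

from barcodekit.io import BarcodeAlignment, SpecimenRecord
from barcodekit.simulate import gapped_preset, simulate_dataset


def make_alignment(seqs: dict[str, str], species: dict[str, str] | None = None,
                   marker: str = "COI-like") -> BarcodeAlignment:
    """Construct a validated alignment from literal sequences."""
    species = species or {sid: f"m_{sid}" for sid in seqs}
    records = {sid: SpecimenRecord(sid, species[sid], marker) for sid in seqs}
    return BarcodeAlignment(ids=list(seqs), seqs=list(seqs.values()),
                            records=records, marker=marker)


@pytest.fixture(scope="session")
def gapped_dataset():
    """The clean-recovery dataset: 20 clonal species, 5 sequences each."""
    return simulate_dataset(gapped_preset(n_species=20, seqs_per_species=5, seed=42))


@pytest.fixture(scope="session")
def gapped_k2p(gapped_dataset):
    from barcodekit.distances import distance_matrix

    return distance_matrix(gapped_dataset.alignment, model="k2p")


def write_fasta(path, seqs: dict[str, str]):
    path.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))


def write_metadata(path, species: dict[str, str], marker="COI-like"):
    lines = ["specimen_id\tmorphospecies\tmarker"]
    lines += [f"{sid}\t{sp}\t{marker}" for sid, sp in species.items()]
    path.write_text("\n".join(lines) + "\n")


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
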