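import numpy as np
import pytest

from driverec import MethodOutput, MutationTable, SyntheticConfig, simulate_cohort

# 5-node toy graph used across feature tests:
#   interior genes (module): A, B, C;  exterior: D, E
TOY_EDGES = [
    ("A", "B", 0.5),
    ("A", "C", 0.2),
    ("B", "C", 0.9),
    ("D", "A", 0.4),
    ("D", "B", 0.1),
    ("D", "C", 0.3),
    ("E", "D", 0.7),
]


@pytest.fixture
def toy_module_count_output():
    return MethodOutput(
        method_id="netbox",
        kind="module_count",
        modules=[{"A", "B", "C"}],
        network=TOY_EDGES,
    )


@pytest.fixture
def toy_module_weighted_output():
    return MethodOutput(
        method_id="flnp",
        kind="module_weighted",
        modules=[{"A", "B", "C"}],
        network=TOY_EDGES,
    )


@pytest.fixture
def toy_maf_lines():
    """MAF text reproducing the worked mutation-rate examples: one gene with
    6 non-silent + 1 silent mutation in 7 samples, one with 3 missense in 3
    samples, plus an unrelated twice-mutated gene."""
    rows = [["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification",
             "Extra_Col"]]
    for i in range(5):
        rows.append(["PRKCQ", f"BR{i:02d}", "Missense_Mutation", "x"])
    rows.append(["PRKCQ", "BR05", "Nonsense_Mutation", "x"])
    rows.append(["PRKCQ", "BR06", "Silent", "x"])
    for i in range(3):
        rows.append(["PRKD3", f"OV{i:02d}", "Missense_Mutation", "x"])
    rows.append(["TWICE", "BR00", "Missense_Mutation", "x"])
    rows.append(["TWICE", "BR01", "Missense_Mutation", "x"])
    return "# version 1.0\n" + "\n".join("\t".join(r) for r in rows) + "\n"


@pytest.fixture
def toy_maf(tmp_path, toy_maf_lines):
    path = tmp_path / "toy.maf"
    path.write_text(toy_maf_lines)
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured synthetic cohort shared across tests."""
    cfg = SyntheticConfig(n_genes=300, n_drivers=20, n_samples=200, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture
def separable_training_data():
    """Linearly separable 2-class data in 10-D."""
    rng = np.random.default_rng(42)
    X = np.vstack(
        [rng.normal(0.0, 0.5, (37, 10)), rng.normal(4.0, 0.5, (37, 10))]
    )
    y = np.r_[np.zeros(37, dtype=int), np.ones(37, dtype=int)]
    return X, y
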