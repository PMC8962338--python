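import warnings

import pytest

warnings.filterwarnings("ignore", message="lbfgs failed to converge")

# small battery of structurally diverse molecules used by the oracle and
# invariance tests (kept <= 8 bonds / 8 heavy atoms where the brute-force
# oracles require it)
SMALL_MOLECULES = [
    "CC",
    "CCC",
    "CCCC",
    "CC(C)C",
    "CC(C)(C)C",
    "CCCCC",
    "CC(C)CC",
    "CCO",
    "COC",
    "CCN",
    "CC(=O)O",
    "C1CC1",
    "C1CCC1",
    "C1CCCC1",
    "C1CCCCC1",
    "c1ccccc1",
    "c1ccncc1",
    "CC#N",
    "C=CC=C",
    "FC(F)F",
    "ClCCBr",
    "CC1CC1",
    "OCC=O",
]


@pytest.fixture(scope="session")
def synth_run():
    """One full pipeline run on the default synthetic dataset (Model-2
    descriptors), shared across modeling/interpretation tests."""
    import tempfile
    from pathlib import Path

    from ptml import RunConfig, SyntheticConfig, run_pipeline
    from ptml.synthetic_fixtures import write_dataset

    tmp = Path(tempfile.mkdtemp(prefix="ptml_synth_"))
    csv = tmp / "synth.csv"
    write_dataset(SyntheticConfig(seed=1), csv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(
            RunConfig(input_csv=str(csv), out_dir=str(tmp / "out"), model=2),
            write=False,
        )
    return result


@pytest.fixture(scope="session")
def micro():
    """The hand-checked 8-molecule micro fixture and its companion
    expected values."""
    from ptml import generate_worked_micro_dataset, micro_expected

    return generate_worked_micro_dataset(), micro_expected()
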